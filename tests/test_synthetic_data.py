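"""NNK library simulation: enumeration, WT fraction, effects, counts, FASTQ."""

import numpy as np
import pytest

from operon_dms import synthetic_data as sd
from operon_dms.core import NNK_CODONS, WT_ROW_ID, OperonSpec


def test_nnk_alphabet():
    assert len(NNK_CODONS) == 32
    assert all(c[2] in "GT" for c in NNK_CODONS)


def test_enumerate_single_position(toy_spec):
    spec = OperonSpec("g", toy_spec.coding_sequence, [2])
    variants = sd.enumerate_nnk_variants(spec)
    assert len(variants) == 32
    assert all(v.position == 2 and v.wt_codon == "AAA" for v in variants)


def test_enumerate_full_saturation_count():
    # 71 mutagenized positions x 32 NNK codons
    gene = sd.random_gene(72, seed=3)
    spec = OperonSpec("g", gene, list(range(2, 73)))
    assert len(sd.enumerate_nnk_variants(spec)) == 2272


def test_nnk_nonsense_is_tag_only(toy_spec):
    variants = sd.enumerate_nnk_variants(toy_spec)
    stops = {v.mut_codon for v in variants if v.kind == "nonsense"}
    assert stops == {"TAG"}


def test_enumerate_rejects_bad_position(toy_spec):
    with pytest.raises(ValueError, match="7"):
        OperonSpec("g", toy_spec.coding_sequence, [7])


@pytest.mark.parametrize(
    "codons,carryover,expected",
    [
        # every WT codon K-ending -> each pool regenerates WT once
        (["AAG", "CTG", "GGT"], 0.0, 1 / 32),
        # no WT codon K-ending -> NNK never regenerates WT
        (["AAA", "CTC", "GGA"], 0.0, 0.0),
        # 2 of 4 K-ending
        (["AAG", "CTC", "GGT", "TCA"], 0.0, 2 / (4 * 32)),
        # carryover adds on top of the NNK-borne fraction
        (["AAG"], 0.073, 0.073 + (1 - 0.073) / 32),
    ],
)
def test_expected_wt_fraction(codons, carryover, expected):
    gene = "ATG" + "".join(codons)
    spec = OperonSpec("g", gene, list(range(2, 2 + len(codons))))
    assert sd.expected_wt_fraction(spec, carryover) == pytest.approx(expected)


class TestAssignTrueEffects:
    def _variants(self, toy_spec):
        return sd.enumerate_nnk_variants(toy_spec)

    def test_seeded_determinism(self, toy_spec):
        variants = self._variants(toy_spec)
        model = sd.EffectModel(noise_sd=0.5, seed=42)
        a = sd.assign_true_effects(variants, model, spec=toy_spec)
        b = sd.assign_true_effects(variants, model, spec=toy_spec)
        np.testing.assert_array_equal(a.true_survival, b.true_survival)

    def test_null_model_gives_baseline(self, toy_spec):
        variants = self._variants(toy_spec)
        model = sd.EffectModel(baseline_survival=2.0, nonsense_survival=1.0)
        lib = sd.assign_true_effects(variants, model, spec=toy_spec)
        np.testing.assert_allclose(lib.true_survival, 2.0)

    def test_survival_increases_with_rcu(self, toy_spec):
        variants = [v for v in self._variants(toy_spec) if v.kind not in ("nonsense", "wt")]
        rng = np.random.default_rng(0)
        rcu_map = {v.variant_id: float(10 ** rng.uniform(-1, 1)) for v in variants}
        model = sd.EffectModel(rcu_coefficient=1.0)
        lib = sd.assign_true_effects(variants, model, rcu_map, spec=toy_spec)
        order = np.argsort([rcu_map[v.variant_id] for v in variants])
        surv_sorted = lib.true_survival[order]
        assert (np.diff(surv_sorted) > 0).all()

    def test_missing_rcu_raises(self, toy_spec):
        variants = self._variants(toy_spec)
        model = sd.EffectModel(rcu_coefficient=1.0)
        with pytest.raises(ValueError, match="RCU"):
            sd.assign_true_effects(variants, model, {}, spec=toy_spec)

    def test_region_offsets_apply(self, toy_spec):
        variants = [v for v in self._variants(toy_spec) if v.kind == "nonsynonymous"]
        model = sd.EffectModel(region_effects={(5, 6): -2.0})
        lib = sd.assign_true_effects(variants, model, spec=toy_spec)
        for v, s in zip(variants, lib.true_survival):
            expected = np.exp(-2.0) if 5 <= v.position <= 6 else 1.0
            assert s == pytest.approx(expected)


class TestSimulateCounts:
    def _library(self, toy_spec, survivals=None):
        variants = sd.enumerate_nnk_variants(toy_spec)
        if survivals is None:
            survivals = np.ones(len(variants))
        return sd.library_from_survivals(toy_spec, variants, survivals)

    def test_column_sums_equal_depth(self, toy_spec):
        lib = self._library(toy_spec)
        cfg = sd.SimConfig(depth_per_replicate=5000, n_replicates=3, seed=7)
        table = sd.simulate_counts(lib, cfg)
        assert (table.totals == 5000).all()

    def test_wt_identical_variants_fold_into_wt(self, toy_spec):
        lib = self._library(toy_spec)
        cfg = sd.SimConfig(depth_per_replicate=5000, seed=7)
        table = sd.simulate_counts(lib, cfg)
        assert not any("wt" == k for k in table.variants["kind"])
        # WT row receives ~wt_fraction + wt-identical pool share
        n_wt_like = sum(v.kind == "wt" for v in lib.variants)
        expected = 0.10 + 0.90 * n_wt_like / len(lib.variants)
        frac = table.counts.loc[WT_ROW_ID].sum() / table.counts.to_numpy().sum()
        assert frac == pytest.approx(expected, abs=0.02)

    def test_neutral_selection_preserves_proportions(self, toy_spec):
        # all survivals 1 -> selected fractions match unselected within noise
        lib = self._library(toy_spec)
        cfg = sd.SimConfig(depth_per_replicate=100_000, n_replicates=1, seed=11)
        table = sd.simulate_counts(lib, cfg)
        pre = table.counts[("unselected", 1)]
        post = table.counts[("selected", 1)]
        p = pre / pre.sum()
        se = np.sqrt(p * (1 - p) / pre.sum())
        resid = (post / post.sum() - p).abs()
        assert (resid <= 4 * se + 1e-12).mean() > 0.99

    def test_selection_depletes_low_survival_variant(self, toy_spec):
        variants = sd.enumerate_nnk_variants(toy_spec)
        surv = np.ones(len(variants))
        surv[0] = 0.1
        lib = sd.library_from_survivals(toy_spec, variants, surv)
        cfg = sd.SimConfig(depth_per_replicate=100_000, n_replicates=1, seed=13)
        table = sd.simulate_counts(lib, cfg)
        vid = variants[0].variant_id
        pre = table.counts.loc[vid, ("unselected", 1)]
        post = table.counts.loc[vid, ("selected", 1)]
        wt_pre = table.counts.loc[WT_ROW_ID, ("unselected", 1)]
        wt_post = table.counts.loc[WT_ROW_ID, ("selected", 1)]
        es = (post / wt_post) / (pre / wt_pre)
        se = 0.1 * np.sqrt(1 / pre + 1 / max(post, 1))
        assert es == pytest.approx(0.1, abs=3 * se)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            sd.SimConfig(depth_per_replicate=0)


class TestEmitFastq:
    def test_reads_reconstruct_templates_and_tags(self, toy_spec, tmp_path):
        variants = sd.enumerate_nnk_variants(toy_spec)
        lib = sd.library_from_survivals(toy_spec, variants, np.ones(len(variants)))
        cfg = sd.SimConfig(depth_per_replicate=500, n_replicates=1, seed=3)
        table = sd.simulate_counts(lib, cfg)
        (r1, r2), = sd.emit_fastq(lib, table, cfg, str(tmp_path / "reads"))
        from operon_dms.core import revcomp
        from operon_dms.read_processing import _fastq_pairs

        tags = set(cfg.mid_tags.values())
        n = 0
        for _rid, s1, _q1, s2, _q2 in _fastq_pairs(r1, r2):
            assert s1[:6] in tags and s2[:6] == s1[:6]
            assert revcomp(s2[6:]) == s1[6:]  # error rate 0: exact template
            n += 1
        assert n == 1000  # both conditions at depth 500

    def test_fastq_byte_identical_for_same_seed(self, toy_spec, tmp_path):
        variants = sd.enumerate_nnk_variants(toy_spec)
        lib = sd.library_from_survivals(toy_spec, variants, np.ones(len(variants)))
        cfg = sd.SimConfig(depth_per_replicate=200, n_replicates=1,
                           sequencing_error_rate=0.01, seed=5)
        table = sd.simulate_counts(lib, cfg)
        (a1, _), = sd.emit_fastq(lib, table, cfg, str(tmp_path / "a"))
        (b1, _), = sd.emit_fastq(lib, table, cfg, str(tmp_path / "b"))
        assert open(a1).read() == open(b1).read()

    def test_duplicate_tags_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            sd.SimConfig(mid_tags={"unselected": "ACGTAC", "selected": "ACGTAC"})
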