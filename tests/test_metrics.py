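"""TMB, mutator class, MSI score, substitution spectrum, CNA calling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from enoc_strat.io_model import MutatorClass, SPECTRUM_CLASSES
from enoc_strat.metrics import (
    call_cna,
    classify_mutator,
    compute_msi_score,
    compute_spectrum,
    compute_tmb,
)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class TestTmb:
    def test_counts_variants(self, call_factory):
        variants = [call_factory(pos=i) for i in range(1, 79)]
        assert compute_tmb(variants) == 78

    def test_empty_is_zero(self):
        assert compute_tmb([]) == 0

    def test_duplicates_by_key_count_once(self, call_factory):
        a = call_factory(pos=100, ref="ATT", alt="AT")
        b = call_factory(pos=101, ref="TT", alt="T")  # same deletion re-anchored
        assert compute_tmb([a, b]) == 1

    def test_mixed_samples_rejected(self, call_factory):
        with pytest.raises(ValueError):
            compute_tmb([call_factory(sample_id="S1"), call_factory(sample_id="S2", pos=2)])


class TestMutatorClass:
    @pytest.mark.parametrize(
        "tmb,expected",
        [
            (0, MutatorClass.NORMAL),
            (78, MutatorClass.NORMAL),
            (250, MutatorClass.NORMAL),
            (251, MutatorClass.HYPERMUTATED),
            (1000, MutatorClass.HYPERMUTATED),
            (1001, MutatorClass.ULTRAMUTATED),
            (2894, MutatorClass.ULTRAMUTATED),
        ],
    )
    def test_boundaries(self, tmb, expected):
        assert classify_mutator(tmb) is expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_mutator(-1)


class TestMsiScore:
    def test_counts_short_indels_only(self, call_factory):
        indels = [call_factory(pos=i, ref="AT", alt="A") for i in (1, 2, 3)]
        snvs = [call_factory(pos=i) for i in (10, 11, 12, 13, 14)]
        assert compute_msi_score(indels + snvs) == 3

    def test_snvs_only_zero(self, call_factory):
        assert compute_msi_score([call_factory(pos=i) for i in range(1, 6)]) == 0

    def test_long_indel_excluded(self, call_factory):
        v = call_factory(ref="A" + "T" * 12, alt="A")  # 12-bp deletion
        assert compute_msi_score([v], max_indel_len=5) == 0

    def test_never_exceeds_tmb_and_monotone(self, call_factory, rng):
        variants = [
            call_factory(pos=int(p), ref="AT" if rng.random() < 0.3 else "C",
                         alt="A" if rng.random() < 0.3 else "T")
            for p in rng.choice(10**6, 50, replace=False)
        ]
        variants = [v for v in variants if v.ref != v.alt]
        msi, tmb = compute_msi_score(variants), compute_tmb(variants)
        assert msi <= tmb
        extra = call_factory(pos=10**7, ref="AT", alt="A")
        assert compute_msi_score(variants + [extra]) == msi + 1


class TestSpectrum:
    def test_strand_collapse_g_to_a_is_c_to_t(self, call_factory):
        variants = [
            call_factory(pos=1, ref="C", alt="T"),
            call_factory(pos=2, ref="G", alt="A"),
        ]
        spec = dict(zip(SPECTRUM_CLASSES, compute_spectrum(variants)))
        assert spec["C>T"] == pytest.approx(1.0)

    def test_one_of_each_class_uniform(self, call_factory):
        variants = [
            call_factory(pos=i + 1, ref=c.split(">")[0], alt=c.split(">")[1])
            for i, c in enumerate(SPECTRUM_CLASSES)
        ]
        assert compute_spectrum(variants) == pytest.approx((1 / 6,) * 6)

    def test_matches_exhaustive_tally(self, call_factory, rng):
        variants = []
        for i in range(100):
            ref = "ACGT"[rng.integers(4)]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(call_factory(pos=i + 1, ref=ref, alt=str(alt)))
        # independent brute-force tally
        tally = {c: 0 for c in SPECTRUM_CLASSES}
        for v in variants:
            ref, alt = v.ref, v.alt
            if ref in "AG":
                ref, alt = COMP[ref], COMP[alt]
            tally[f"{ref}>{alt}"] += 1
        expected = tuple(tally[c] / 100 for c in SPECTRUM_CLASSES)
        assert compute_spectrum(variants) == pytest.approx(expected)

    def test_complement_invariance(self, call_factory, rng):
        variants = []
        for i in range(60):
            ref = "ACGT"[rng.integers(4)]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            variants.append(call_factory(pos=i + 1, ref=ref, alt=alt))
        complemented = [
            call_factory(pos=v.pos, ref=COMP[v.ref], alt=COMP[v.alt])
            for v in variants
        ]
        assert compute_spectrum(variants) == pytest.approx(
            compute_spectrum(complemented)
        )

    def test_no_snvs_gives_zero_vector(self, call_factory):
        indel = call_factory(ref="AT", alt="A")
        assert compute_spectrum([indel]) == (0.0,) * 6


class TestCallCna:
    def _matrix(self, rng, n_genes=100, n_ref=20, n_test=5):
        genes = [f"G{i}" for i in range(n_genes)]
        cols = [f"R{i}" for i in range(n_ref)] + [f"T{i}" for i in range(n_test)]
        return pd.DataFrame(
            rng.normal(0, 1, (n_genes, n_ref + n_test)), index=genes, columns=cols
        )

    def test_sample_at_reference_mean_has_no_events(self, rng):
        m = self._matrix(rng)
        ref_cols = [c for c in m.columns if c.startswith("R")]
        m["T0"] = m[ref_cols].mean(axis=1)
        events = call_cna(m, ref_cols)
        assert events["T0"] == []

    def test_planted_amplifications_recovered(self, rng):
        m = self._matrix(rng)
        ref_cols = [c for c in m.columns if c.startswith("R")]
        sd = m[ref_cols].std(axis=1, ddof=1)
        for g in ("G3", "G40", "G77"):
            m.loc[g, "T1"] = m.loc[g, ref_cols].mean() + 8 * sd[g]
        events = call_cna(m, ref_cols, sd_threshold=5.0)
        assert events["T1"] == [("G3", "gain"), ("G40", "gain"), ("G77", "gain")]

    def test_loss_direction(self, rng):
        m = self._matrix(rng)
        ref_cols = [c for c in m.columns if c.startswith("R")]
        sd = m[ref_cols].std(axis=1, ddof=1)
        m.loc["G10", "T2"] = m.loc["G10", ref_cols].mean() - 7 * sd["G10"]
        assert ("G10", "loss") in call_cna(m, ref_cols)["T2"]

    def test_zero_variance_gene_skipped(self, rng):
        m = self._matrix(rng, n_genes=10)
        ref_cols = [c for c in m.columns if c.startswith("R")]
        m.loc["G0", ref_cols] = 1.0
        m.loc["G0", "T0"] = 100.0
        events = call_cna(m, ref_cols)
        assert all(g != "G0" for g, _ in events["T0"])

    def test_reference_false_positive_rate_near_nominal(self, rng):
        """On null data at sd_threshold=2 the per-gene call rate is ~2*Phi(-2)."""
        m = self._matrix(rng, n_genes=400, n_ref=100, n_test=100)
        ref_cols = [c for c in m.columns if c.startswith("R")]
        events = call_cna(m, ref_cols, sd_threshold=2.0, alpha=1.0)
        test_cols = [c for c in m.columns if c.startswith("T")]
        rate = sum(len(events[c]) for c in test_cols) / (400 * 100)
        expected = 2 * norm.sf(2.0)
        assert rate == pytest.approx(expected, rel=0.25)
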