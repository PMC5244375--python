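import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from triomic.cnv import (
    Segment,
    SampleNoise,
    call_segment_status,
    compute_cn_frequencies,
    estimate_sample_noise,
    format_fraction,
    gene_cn_status,
    implied_min_tumours,
    max_arc_statistic,
    normalize_within_array,
    probe_status_from_segments,
    segment_cbs,
    segment_sample,
)
from triomic.genome import ProbeLocus


def brute_force_max_arc(x, min_width=2):
    """Exhaustive O(n^2) arc enumeration oracle."""
    n = len(x)
    best = (-np.inf, 0, n)
    for i in range(n + 1):
        for j in range(i + min_width, n + 1):
            k = j - i
            if n - k < min_width:
                continue
            arc = x[i:j]
            comp = np.concatenate([x[:i], x[j:]])
            s = abs(arc.mean() - comp.mean()) / np.sqrt(1 / k + 1 / (n - k))
            if s > best[0]:
                best = (s, i, j)
    return best


def cuts(i, j, n):
    return {c for c in (i, j) if 0 < c < n}


class TestMaxArcStatistic:
    @given(st.integers(min_value=5, max_value=40), st.integers(min_value=0, max_value=10**6))
    @settings(derandomize=True, max_examples=40)
    def test_agrees_with_exhaustive_search(self, n, seed):
        """Value and induced split match brute-force arc enumeration (an arc
        and its complement define the same partition)."""
        x = np.random.default_rng(seed).normal(0, 1, n)
        s1, i1, j1 = max_arc_statistic(x)
        s2, i2, j2 = brute_force_max_arc(x)
        assert s1 == pytest.approx(s2, rel=1e-9)
        assert cuts(i1, j1, n) == cuts(i2, j2, n) or s1 == pytest.approx(s2, rel=1e-12)


class TestSegmentation:
    def test_noiseless_step_recovered_exactly(self):
        x = np.array([0.0] * 20 + [1.0] * 20)
        segs = segment_cbs(x, np.arange(40) * 4000, n_perm=500, seed=1)
        assert [(s.start_probe_index, s.end_probe_index) for s in segs] == [(0, 19), (20, 39)]
        assert [s.mean_log2 for s in segs] == [0.0, 1.0]

    def test_constant_signal_single_segment(self):
        segs = segment_cbs(np.full(30, 0.7), np.arange(30), n_perm=500, seed=0)
        assert len(segs) == 1 and segs[0].n_probes == 30

    def test_empty_chromosome(self):
        assert segment_cbs(np.array([]), np.array([]), seed=0) == []

    def test_noisy_step_boundary_within_one_probe(self):
        """Height-1 step under N(0, 0.2) noise (SNR 5): detected boundary is
        within +-1 probe of truth and the chosen split equals exhaustive
        arc search."""
        rng = np.random.default_rng(7)
        x = np.concatenate([np.zeros(25), np.ones(25)]) + rng.normal(0, 0.2, 50)
        _, i, j = max_arc_statistic(x)
        sb, ib, jb = brute_force_max_arc(x)
        assert cuts(i, j, 50) == cuts(ib, jb, 50)
        segs = segment_cbs(x, np.arange(50) * 4000, n_perm=1000, seed=2)
        boundaries = {s.start_probe_index for s in segs[1:]}
        assert any(abs(b - 25) <= 1 for b in boundaries)

    def test_partition_invariant(self):
        """Segments tile the probe sequence without gaps or overlaps and
        means equal the member-probe means."""
        rng = np.random.default_rng(3)
        x = rng.normal(0, 0.3, 80)
        x[30:50] += 1.2
        segs = segment_cbs(x, np.arange(80), n_perm=300, seed=4)
        assert sum(s.n_probes for s in segs) == 80
        edges = sorted((s.start_probe_index, s.end_probe_index) for s in segs)
        assert edges[0][0] == 0 and edges[-1][1] == 79
        for (a, b), (c, d) in zip(edges[:-1], edges[1:]):
            assert c == b + 1
        for s in segs:
            assert s.mean_log2 == pytest.approx(
                x[s.start_probe_index : s.end_probe_index + 1].mean(), abs=1e-9
            )


class TestSampleNoise:
    def test_zero_residuals(self):
        segs = [Segment("s", "1", 0, 2, 0, 2, 1.0, 3)]
        noise = estimate_sample_noise({"1": np.array([1.0, 1.0, 1.0])}, segs, "s")
        assert noise.mad_residual == 0.0

    def test_hand_computed_mad(self):
        """Residuals {-1, 0, 1}: median 0, absolute deviations {1, 0, 1},
        MAD = 1 (unscaled)."""
        segs = [Segment("s", "1", 0, 2, 0, 2, 0.0, 3)]
        noise = estimate_sample_noise({"1": np.array([-1.0, 0.0, 1.0])}, segs, "s")
        assert noise.mad_residual == 1.0

    def test_median_segment_of_autosomes(self):
        segs = [
            Segment("s", "1", 0, 1, 0, 1, 0.0, 2),
            Segment("s", "2", 0, 1, 0, 1, 0.6, 2),
            Segment("s", "x", 0, 1, 0, 1, 9.9, 2),  # excluded from the median
        ]
        observed = {"1": np.zeros(2), "2": np.full(2, 0.6), "x": np.full(2, 9.9)}
        noise = estimate_sample_noise(observed, segs, "s")
        assert noise.median_segment == pytest.approx(0.3)


class TestStatusCalls:
    @pytest.mark.parametrize(
        "mean,expected", [(0.25, "gain"), (-0.15, "neutral"), (-0.30, "loss")]
    )
    def test_two_mad_rule(self, mean, expected):
        seg = Segment("s", "1", 0, 0, 0, 0, mean, 1)
        noise = SampleNoise("s", mad_residual=0.1, median_segment=0.0)
        (out,) = call_segment_status([seg], noise, k=2)
        assert out.status == expected

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            call_segment_status([], SampleNoise("s", 0.1, 0.0), k=0)

    def test_mad_floor_guards_noiseless_samples(self):
        seg = Segment("s", "1", 0, 0, 0, 0, 0.005, 1)
        noise = SampleNoise("s", mad_residual=0.0, median_segment=0.0)
        (out,) = call_segment_status([seg], noise, mad_floor=0.01)
        assert out.status == "neutral"

    def test_agrees_with_brute_force_predicate(self):
        """Status calls equal a direct per-segment threshold check on random
        instances."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            means = rng.normal(0, 0.5, rng.integers(3, 12))
            segs = [Segment("s", "1", i, i, i, i, m, 1) for i, m in enumerate(means)]
            mad = float(rng.uniform(0.02, 0.3))
            med = float(rng.normal(0, 0.2))
            noise = SampleNoise("s", mad, med)
            out = call_segment_status(segs, noise, k=2)
            for s in out:
                if s.mean_log2 > med + 2 * mad:
                    assert s.status == "gain"
                elif s.mean_log2 < med - 2 * mad:
                    assert s.status == "loss"
                else:
                    assert s.status == "neutral"

    def test_scale_equivariance(self):
        """Multiplying a sample by c > 0 scales means and MAD by c and leaves
        every status unchanged."""
        rng = np.random.default_rng(4)
        x = rng.normal(0, 0.2, 60)
        x[20:40] += 1.0
        pos = np.arange(60) * 4000
        c = 3.7
        for scale in (1.0, c):
            segs = segment_cbs(x * scale, pos, n_perm=300, seed=5, chromosome="1")
            noise = estimate_sample_noise({"1": x * scale}, segs)
            segs = call_segment_status(segs, noise)
            if scale == 1.0:
                ref_status = [s.status for s in segs]
                ref_means = [s.mean_log2 for s in segs]
                ref_mad = noise.mad_residual
            else:
                assert [s.status for s in segs] == ref_status
                np.testing.assert_allclose([s.mean_log2 for s in segs], np.array(ref_means) * c)
                assert noise.mad_residual == pytest.approx(ref_mad * c)


class TestFrequencies:
    def test_one_third_cutoff_on_twelve_tumours(self):
        cols = [f"T{i}" for i in range(12)]
        rows = {
            "p4": ["gain"] * 4 + ["neutral"] * 8,
            "p3": ["gain"] * 3 + ["neutral"] * 9,
            "p12": ["gain"] * 12,
        }
        status = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
        f = compute_cn_frequencies(status, 1 / 3)
        assert bool(f.loc["p4", "common_amplified"]) is True
        assert bool(f.loc["p3", "common_amplified"]) is False
        assert f.loc["p12", "gain_fraction"] == 1.0 and bool(f.loc["p12", "common_amplified"])

    def test_implied_minimum_tumour_count(self):
        assert implied_min_tumours(1 / 3, 12) == 4
        assert implied_min_tumours(0.25, 12) == 3
        assert implied_min_tumours(1 / 3, 10) == 4

    def test_rejects_zero_tumours(self):
        with pytest.raises(ValueError):
            compute_cn_frequencies(pd.DataFrame(index=["p"]), 1 / 3)


class TestGeneStatus:
    def _status(self):
        cols = [f"T{i}" for i in range(12)]
        data = {f"p{i}": ["neutral"] * 12 for i in range(5)}
        df = pd.DataFrame.from_dict(data, orient="index", columns=cols)
        return df

    def test_majority_and_tie_rules(self):
        df = self._status()
        df.loc["p0", "T0"] = "gain"
        df.loc["p1", "T0"] = "gain"
        df.loc["p2", "T0"] = "gain"  # gene A: (gain, gain, gain, neutral x2)? use subsets
        mapping = {"A": ["p0", "p1", "p2"], "B": ["p3", "p4"]}
        df.loc["p3", "T1"] = "gain"
        df.loc["p4", "T1"] = "loss"
        status, rec, unmapped = gene_cn_status(df, mapping, set(), 1 / 3)
        assert status.loc["A", "T0"] == "gain"
        assert status.loc["B", "T1"] == "neutral"  # gain/loss tie
        assert unmapped == []

    def test_intergenic_probes_excluded_and_unmapped_listed(self):
        df = self._status()
        mapping = {"A": ["p0"], "B": ["pX"]}
        status, rec, unmapped = gene_cn_status(df, mapping, {"p0"}, 1 / 3)
        assert unmapped == ["A", "B"]

    def test_recurrence_fraction_formatting(self):
        """A gene altered in 5 of 12 tumours is reported as 41.7%."""
        df = self._status()
        for t in range(5):
            df.loc["p0", f"T{t}"] = "loss"
        status, rec, _ = gene_cn_status(df, {"A": ["p0"]}, set(), 1 / 3)
        assert rec.loc["A", "loss_freq_label"] == "41.7%, 5/12"
        assert bool(rec.loc["A", "deleted"]) is True
        assert format_fraction(5, 12) == "41.7%, 5/12"


class TestNormalization:
    def _probes(self, n, gc=None, grid=False, side=None):
        rng = np.random.default_rng(0)
        gc = rng.uniform(0.3, 0.7, n) if gc is None else gc
        side = side or int(np.ceil(np.sqrt(n)))
        return [
            ProbeLocus(
                f"p{i}", "1", i * 4000, float(gc[i]),
                (i // side) if grid else None, (i % side) if grid else None,
            )
            for i in range(n)
        ]

    def test_no_bias_reduces_to_median_centering(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0.2, 0.1, 200)
        probes = self._probes(200, gc=np.full(200, 0.5))
        out = normalize_within_array(v, probes)
        np.testing.assert_allclose(out, v - np.median(v), atol=1e-12)

    def test_gc_trend_removed(self):
        """A linear GC trend plus a step: the corrected values recover the
        step up to centering, with residual bias below 5% of the trend
        coefficient."""
        rng = np.random.default_rng(2)
        n, beta = 400, 4.0
        gc = rng.uniform(0.3, 0.7, n)
        step = np.where(np.arange(n) < n // 2, 0.0, 1.0)
        v = beta * (gc - 0.5) + step
        out = normalize_within_array(v, self._probes(n, gc=gc))
        target = step - np.median(step)
        assert np.max(np.abs(out - target)) < 0.05 * beta

    def test_spatial_sinusoid_attenuated(self):
        """A pure low-frequency spatial wave (one cycle across the grid) is
        suppressed to under 10% of its amplitude."""
        n, side = 4096, 64
        probes = self._probes(n, gc=np.full(n, 0.5), grid=True, side=side)
        r = np.arange(n) // side
        c = np.arange(n) % side
        amp = 0.5
        v = amp * np.sin(2 * np.pi * r / side) * np.cos(2 * np.pi * c / side)
        out = normalize_within_array(v, probes)
        assert np.max(np.abs(out)) < 0.1 * amp


class TestPlantedRecovery:
    def test_probe_level_sensitivity_and_precision(self):
        """Planted |log2| 0.58 events of >= 20 probes at noise sd 0.15 are
        called at probe level with sensitivity and precision >= 0.9
        (10 seeded replicates)."""
        sens_all, prec_all = [], []
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            n = 200
            x = rng.normal(0, 0.15, n)
            truth = np.array(["neutral"] * n, dtype=object)
            x[40:70] += 0.58
            truth[40:70] = "gain"
            x[120:145] -= 0.58
            truth[120:145] = "loss"
            probes = [ProbeLocus(f"p{i}", "1", i * 4000, 0.5) for i in range(n)]
            values = pd.Series(x, index=[p.probe_id for p in probes])
            _, _, status = segment_sample(
                values, probes, "s", n_perm=200, seed=rep
            )
            called = status.loc[[p.probe_id for p in probes]].to_numpy()
            aberrant = truth != "neutral"
            tp = np.sum((called == truth) & aberrant)
            sens_all.append(tp / aberrant.sum())
            called_ab = called != "neutral"
            prec_all.append(
                np.sum((called == truth) & aberrant) / max(called_ab.sum(), 1)
            )
        assert np.mean(sens_all) >= 0.9
        assert np.mean(prec_all) >= 0.9

    def test_noiseless_gain_yields_exactly_the_overlapping_genes(self):
        """With zero noise and one planted gain, the recurrent gene list is
        exactly the genes overlapping the event."""
        from triomic.genome import map_probes_to_genes
        from triomic.simulate import CnaEvent, CohortConfig, simulate_cohort

        cfg = CohortConfig(
            seed=2, n_chromosomes=1, chrom_length_bp=600_000, n_genes=12,
            cna_events=[CnaEvent("1", 150_000, 290_000, "gain", 0.6, 1.0)],
            noise_sd_cgh=0, noise_sd_meth=0, noise_sd_expr=0,
        )
        c = simulate_cohort(cfg)
        status_cols = {}
        for i, s in enumerate(c.tumour_ids):
            _, _, status = segment_sample(c.cgh_ratios[s], c.cgh_probes, s, n_perm=200, seed=i)
            status_cols[s] = status
        probe_status = pd.DataFrame(status_cols)
        mapping, intergenic = map_probes_to_genes(c.cgh_probes, c.genes, mode="body")
        _, rec, _ = gene_cn_status(probe_status, mapping, intergenic, 1 / 3)
        called = set(rec.index[rec.amplified])
        expected = {
            g.gene_id for g in c.genes if g.body_start < 290_000 and g.body_end > 150_000
        }
        assert called == expected
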