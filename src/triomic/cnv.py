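"""aCGH copy-number calling: within-array normalization, circular binary
segmentation, MAD-threshold gain/loss calls, and recurrence summaries.

Pipeline per tumour sample:

1. ``normalize_within_array`` — remove the GC trend (lowess of log2 ratio
   against probe GC fraction) and, when array grid coordinates exist, a
   spatial surface (2-D moving median); re-centre to zero median.
2. ``segment_cbs`` — circular binary segmentation: recursively find the
   contiguous arc whose mean differs maximally from its complement
   (t-like statistic), accept the split when a permutation test on the
   probe values rejects homogeneity at ``alpha``, and recurse.
3. ``estimate_sample_noise`` — unscaled MAD of observed-minus-segmented
   residuals as the per-sample noise scale, plus the median autosomal
   segment mean as the per-sample centre.
4. ``call_segment_status`` — a segment is a gain (loss) when its mean lies
   more than ``k`` (default 2) sample-MADs above (below) the median
   segment; probes inherit their segment's status.
5. ``compute_cn_frequencies`` / ``gene_cn_status`` — probe-wise and
   gene-wise gain/loss fractions across tumours with a recurrence cutoff
   (default 1/3 of tumours).

This CBS is a faithful but deliberately plain implementation: max-arc
search is exhaustive, split significance uses raw permutations (with early
stopping once non-significance is certain), and there is no post-hoc
segment pruning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome import ProbeLocus, is_autosome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Segment:
    sample_id: str
    chromosome: str
    start_probe_index: int  # inclusive, in sorted probe order within chromosome
    end_probe_index: int  # inclusive
    start_bp: int
    end_bp: int
    mean_log2: float
    n_probes: int
    status: Literal["gain", "loss", "neutral"] = "neutral"


@dataclass(frozen=True)
class SampleNoise:
    sample_id: str
    mad_residual: float
    median_segment: float


# ---------------------------------------------------------------------------
# Normalization


def normalize_within_array(
    values: np.ndarray,
    probes: Sequence[ProbeLocus],
    gc_span: float = 0.3,
    spatial_window: int = 9,
) -> np.ndarray:
    """Remove GC and spatial bias from one sample's probe log2 ratios.

    The GC effect is a lowess fit of value against ``gc_fraction`` (span
    ``gc_span``), subtracted; if probes carry grid coordinates, a 2-D moving
    median (``spatial_window`` square) over the array surface is also
    subtracted.  The result is re-centred to zero median.
    """
    v = np.asarray(values, float).copy()
    gc = np.array([p.gc_fraction for p in probes])
    if np.ptp(gc) == 0:
        logger.warning("all probes share one GC fraction; GC correction skipped")
    else:
        fit = lowess(v, gc, frac=gc_span, return_sorted=False)
        v = v - fit
    rows = [p.array_row for p in probes]
    cols = [p.array_col for p in probes]
    if all(r is not None for r in rows) and all(c is not None for c in cols):
        r = np.asarray(rows, int)
        c = np.asarray(cols, int)
        grid = np.zeros((r.max() + 1, c.max() + 1))
        counts = np.zeros_like(grid)
        np.add.at(grid, (r, c), v)
        np.add.at(counts, (r, c), 1.0)
        filled = np.divide(grid, counts, out=np.zeros_like(grid), where=counts > 0)
        surface = ndimage.median_filter(filled, size=spatial_window, mode="nearest")
        v = v - surface[r, c]
    return v - np.median(v)


# ---------------------------------------------------------------------------
# Circular binary segmentation


def _centered_cumsum(x: np.ndarray) -> np.ndarray:
    """g[k] = sum(x[:k]) - k * mean(x); g[0] = g[n] = 0."""
    n = len(x)
    g = np.empty(n + 1)
    g[0] = 0.0
    np.cumsum(x, out=g[1:])
    g[1:] -= np.arange(1, n + 1) * (g[n] / n)
    return g


def max_arc_statistic(x: np.ndarray, min_width: int = 2) -> tuple[float, int, int]:
    """Exhaustive search for the arc maximizing the mean-difference statistic.

    Over every contiguous arc ``[i, j)`` with both the arc and its
    complement at least ``min_width`` probes wide, computes
    ``|mean(arc) - mean(complement)| / sqrt(1/k + 1/(n-k))`` and returns
    ``(max_stat, i, j)``.  Circular arcs that wrap around are covered
    implicitly: a wrapped arc is the complement of a contiguous one and
    yields the identical statistic.

    Uses the centred-cumulative-sum identity ``stat(i, j) =
    |g(j) - g(i)| * sqrt(n / (k (n-k)))`` with ``k = j - i``, which is the
    same quantity rearranged (one O(n) pass per arc width).
    """
    x = np.asarray(x, float)
    n = len(x)
    if n < 2 * min_width:
        return 0.0, 0, n
    g = _centered_cumsum(x)
    best, best_i, best_k = -np.inf, 0, n
    for k in range(min_width, n - min_width + 1):
        d = np.abs(g[k:] - g[: n - k + 1])
        i = int(np.argmax(d))
        s = d[i] * np.sqrt(n / (k * (n - k)))
        if s > best:
            best, best_i, best_k = float(s), i, k
    return best, best_i, best_i + best_k


def _max_arc_stat_value(g: np.ndarray, n: int, min_width: int) -> float:
    """Max arc statistic from a precomputed centred cumsum (no argmax)."""
    best = -np.inf
    for k in range(min_width, n - min_width + 1):
        d = float(np.max(np.abs(g[k:] - g[: n - k + 1])))
        s = d * np.sqrt(n / (k * (n - k)))
        if s > best:
            best = s
    return best


def _split_significant(
    x: np.ndarray,
    stat: float,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
) -> bool:
    """Permutation test of the max arc statistic, stopping early once the
    exceedance count guarantees p > alpha."""
    allow = int(np.floor(alpha * n_perm))
    count = 0
    n = len(x)
    for b in range(n_perm):
        perm_stat = _max_arc_stat_value(_centered_cumsum(rng.permutation(x)), n, min_width)
        if perm_stat >= stat:
            count += 1
            if count > allow:
                return False
    p = (1.0 + count) / (1.0 + n_perm)
    return p <= alpha


def segment_cbs(
    values: np.ndarray,
    positions: np.ndarray,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int | np.random.Generator | None = 0,
    sample_id: str = "",
    chromosome: str = "",
) -> list[Segment]:
    """Segment one chromosome's ordered log2 ratios by CBS.

    ``values`` and ``positions`` must be sorted by genomic position.
    Returns segments that partition the probe sequence, with means
    recomputed from member probes.
    """
    values = np.asarray(values, float)
    positions = np.asarray(positions)
    if len(values) != len(positions):
        raise ValueError("values and positions must have equal length")
    n = len(values)
    if n == 0:
        return []
    if n_perm < 100:
        logger.warning("n_perm=%d < 100: split p-values will be unstable", n_perm)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    boundaries: list[tuple[int, int]] = []

    def recurse(lo: int, hi: int) -> None:
        x = values[lo:hi]
        if len(x) < 2 * min_width or np.ptp(x) == 0:
            boundaries.append((lo, hi))
            return
        stat, i, j = max_arc_statistic(x, min_width)
        if stat > 0 and _split_significant(x, stat, alpha, n_perm, min_width, rng):
            cuts = sorted({lo, lo + i, lo + j, hi})
            for a, b in zip(cuts[:-1], cuts[1:]):
                recurse(a, b)
        else:
            boundaries.append((lo, hi))

    recurse(0, n)
    boundaries.sort()
    segs = []
    for lo, hi in boundaries:
        segs.append(
            Segment(
                sample_id=sample_id,
                chromosome=chromosome,
                start_probe_index=lo,
                end_probe_index=hi - 1,
                start_bp=int(positions[lo]),
                end_bp=int(positions[hi - 1]),
                mean_log2=float(np.mean(values[lo:hi])),
                n_probes=hi - lo,
                status="neutral",
            )
        )
    return segs


# ---------------------------------------------------------------------------
# MAD noise estimate and status calls


def estimate_sample_noise(
    observed: Mapping[str, np.ndarray],
    segments: Sequence[Segment],
    sample_id: str = "",
) -> SampleNoise:
    """Per-sample noise scale and centre from the segmented fit.

    ``observed`` maps chromosome -> probe log2 ratios in sorted probe order
    (the order the segments index into).  The MAD is unscaled:
    ``median(|r - median(r)|)`` of observed-minus-segmented residuals.
    ``median_segment`` is the median of autosomal segment means.
    """
    residuals = []
    for seg in segments:
        obs = np.asarray(observed[seg.chromosome], float)
        r = obs[seg.start_probe_index : seg.end_probe_index + 1] - seg.mean_log2
        residuals.append(r)
    r = np.concatenate(residuals) if residuals else np.array([0.0])
    mad = float(np.median(np.abs(r - np.median(r))))
    auto_means = [s.mean_log2 for s in segments if is_autosome(s.chromosome)]
    med_seg = float(np.median(auto_means)) if auto_means else 0.0
    return SampleNoise(sample_id=sample_id, mad_residual=mad, median_segment=med_seg)


def call_segment_status(
    segments: Sequence[Segment],
    noise: SampleNoise,
    k: float = 2.0,
    mad_floor: float = 0.01,
) -> list[Segment]:
    """Declare each segment gain/loss/neutral against the sample's MAD.

    A segment is a gain when its mean exceeds ``median_segment + k * d`` and
    a loss when below ``median_segment - k * d``, with ``d`` the sample MAD
    floored at ``mad_floor`` (the floor guards noiseless data, where a MAD
    of 0 would flag every non-central segment).
    """
    if k <= 0:
        raise ValueError("k must be > 0")
    d = max(noise.mad_residual, mad_floor)
    if noise.mad_residual < mad_floor:
        logger.info("sample %s: MAD %.4g floored at %.4g", noise.sample_id,
                    noise.mad_residual, mad_floor)
    m = noise.median_segment
    out = []
    for s in segments:
        if s.mean_log2 > m + k * d:
            status = "gain"
        elif s.mean_log2 < m - k * d:
            status = "loss"
        else:
            status = "neutral"
        out.append(replace(s, status=status))
    return out


def probe_status_from_segments(
    segments: Sequence[Segment], probe_ids_by_chrom: Mapping[str, Sequence[str]]
) -> pd.Series:
    """Every probe inherits the status of the segment containing it."""
    idx, vals = [], []
    for seg in segments:
        ids = probe_ids_by_chrom[seg.chromosome][
            seg.start_probe_index : seg.end_probe_index + 1
        ]
        idx.extend(ids)
        vals.extend([seg.status] * len(ids))
    return pd.Series(vals, index=idx, name="status")


# ---------------------------------------------------------------------------
# Recurrence across tumours


def implied_min_tumours(frequency_cutoff: float, n_tumours: int) -> int:
    """Smallest tumour count meeting the recurrence cutoff (ceiling when
    ``cutoff * n`` is fractional, e.g. a 33% cutoff on 12 tumours -> 4)."""
    raw = frequency_cutoff * n_tumours
    return int(np.ceil(raw - 1e-9)) if abs(raw - round(raw)) > 1e-9 else int(round(raw))


def compute_cn_frequencies(
    probe_status: pd.DataFrame, frequency_cutoff: float = 1.0 / 3.0
) -> pd.DataFrame:
    """Probe-wise gain/loss fractions over tumours with recurrence flags.

    ``probe_status`` is probes x tumours with values gain/loss/neutral.
    """
    n = probe_status.shape[1]
    if n == 0:
        raise ValueError("no tumour samples")
    gain = (probe_status == "gain").mean(axis=1)
    loss = (probe_status == "loss").mean(axis=1)
    return pd.DataFrame(
        {
            "gain_fraction": gain,
            "loss_fraction": loss,
            "common_amplified": gain >= frequency_cutoff,
            "common_deleted": loss >= frequency_cutoff,
        }
    )


def format_fraction(count: int, total: int) -> str:
    """Gene-frequency report style, e.g. 5 of 12 -> ``"41.7%, 5/12"``."""
    return f"{100.0 * count / total:.1f}%, {count}/{total}"


def gene_cn_status(
    probe_status: pd.DataFrame,
    gene_to_probes: Mapping[str, Sequence[str]],
    intergenic: set[str],
    frequency_cutoff: float = 1.0 / 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Collapse probe statuses to gene statuses and recurrence lists.

    A gene's status in a sample is the majority status among its mapped
    probes (gain/loss tie -> neutral).  Returns ``(gene x sample status,
    per-gene recurrence table, genes with zero mapped probes)``.  The
    recurrence table carries gain/loss fractions, recurrence flags at
    ``frequency_cutoff``, and the formatted frequency strings.
    """
    n_tumours = probe_status.shape[1]
    if n_tumours == 0:
        raise ValueError("no tumour samples")
    rows, unmapped = {}, []
    probe_index = probe_status.index
    for gene_id, probe_ids in gene_to_probes.items():
        ids = [p for p in probe_ids if p not in intergenic and p in probe_index]
        if not ids:
            unmapped.append(gene_id)
            continue
        sub = probe_status.loc[ids]
        n_gain = (sub == "gain").sum(axis=0)
        n_loss = (sub == "loss").sum(axis=0)
        # plurality over all probes: a call must beat both rival counts
        n_neutral = (sub == "neutral").sum(axis=0)
        status = np.where(
            (n_gain > n_loss) & (n_gain > n_neutral),
            "gain",
            np.where((n_loss > n_gain) & (n_loss > n_neutral), "loss", "neutral"),
        )
        rows[gene_id] = status
    status_df = pd.DataFrame.from_dict(rows, orient="index", columns=probe_status.columns)
    status_df = status_df.sort_index()
    gain_n = (status_df == "gain").sum(axis=1)
    loss_n = (status_df == "loss").sum(axis=1)
    rec = pd.DataFrame(
        {
            "gain_fraction": gain_n / n_tumours,
            "loss_fraction": loss_n / n_tumours,
            "n_gain": gain_n,
            "n_loss": loss_n,
        }
    )
    rec["amplified"] = rec["gain_fraction"] >= frequency_cutoff
    rec["deleted"] = rec["loss_fraction"] >= frequency_cutoff
    rec["gain_freq_label"] = [format_fraction(c, n_tumours) for c in gain_n]
    rec["loss_freq_label"] = [format_fraction(c, n_tumours) for c in loss_n]
    return status_df, rec, sorted(unmapped)


# ---------------------------------------------------------------------------
# Whole-sample driver


def segment_sample(
    values: pd.Series,
    probes: Sequence[ProbeLocus],
    sample_id: str,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
    normalize: bool = False,
    autosomes_only: bool = True,
    k: float = 2.0,
    mad_floor: float = 0.01,
) -> tuple[list[Segment], SampleNoise, pd.Series]:
    """Segment and call one sample end to end.

    ``values`` is indexed by probe_id; ``probes`` supply coordinates.
    Returns (status-annotated segments, noise estimate, per-probe status).
    """
    probes = [p for p in probes if not autosomes_only or is_autosome(p.chromosome)]
    by_chrom: dict[str, list[ProbeLocus]] = {}
    for p in sorted(probes, key=lambda p: (p.chromosome, p.position)):
        by_chrom.setdefault(p.chromosome, []).append(p)

    v = values
    if normalize:
        ordered = [p for c in sorted(by_chrom) for p in by_chrom[c]]
        corrected = normalize_within_array(values.loc[[p.probe_id for p in ordered]].to_numpy(), ordered)
        v = pd.Series(corrected, index=[p.probe_id for p in ordered])

    segments: list[Segment] = []
    observed: dict[str, np.ndarray] = {}
    probe_ids_by_chrom: dict[str, list[str]] = {}
    rng = np.random.default_rng(seed)
    for chrom in sorted(by_chrom):
        plist = by_chrom[chrom]
        ids = [p.probe_id for p in plist]
        x = v.loc[ids].to_numpy(float)
        pos = np.array([p.position for p in plist])
        segments.extend(
            segment_cbs(
                x, pos, alpha=alpha, n_perm=n_perm, min_width=min_width,
                seed=rng, sample_id=sample_id, chromosome=chrom,
            )
        )
        observed[chrom] = x
        probe_ids_by_chrom[chrom] = ids
    noise = estimate_sample_noise(observed, segments, sample_id=sample_id)
    segments = call_segment_status(segments, noise, k=k, mad_floor=mad_floor)
    status = probe_status_from_segments(segments, probe_ids_by_chrom)
    return segments, noise, status


def segments_to_frame(segments: Sequence[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "chromosome": s.chromosome,
                "start_bp": s.start_bp,
                "end_bp": s.end_bp,
                "n_probes": s.n_probes,
                "mean_log2": s.mean_log2,
                "status": s.status,
            }
            for s in segments
        ]
    )
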