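"""Promoter methylation calling from capture-array log2 ratios.

Each probe is scored by a one-sided two-sample Kolmogorov–Smirnov test:
the log2 ratios of all probes inside a fixed-length window (default
750 bp) centred on the probe are compared against the rest of the array,
asking whether the window is drawn from a stochastically *larger*
distribution (hypermethylation; hypomethylation is the same test on
negated values).  The score is -log10 of the one-sided p-value, computed
exactly (lattice-path probability) when ``m * n <= 10_000`` and otherwise
by the one-sided asymptotic tail ``exp(-2 m n D+^2 / (m + n))``.

Peaks are maximal runs of at least ``min_probes`` consecutive probes with
score at or above a threshold (default 2) in the same direction.  Peaks
are annotated to genes whose promoter window (default 5 kb upstream to
1 kb downstream of the most-upstream TSS) they overlap by at least 1 bp;
a gene's promoter score is the mean over its overlapping peaks' mean
scores, and the aberrant fraction is the share of the window's
interrogated probes that sit inside called peaks.  Hyper- and
hypomethylation are tabulated separately throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genome import ProbeLocus, PromoterWindow, is_autosome

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300


@dataclass(frozen=True)
class MethPeak:
    sample_id: str
    chromosome: str
    start_bp: int
    end_bp: int
    probe_ids: tuple[str, ...]
    direction: Literal["hyper", "hypo"]
    mean_score: float


# ---------------------------------------------------------------------------
# One-sided two-sample KS


def ks_dplus(window_values: np.ndarray, background_values: np.ndarray) -> tuple[float, int]:
    """One-sided KS statistic D+ = sup_x [F_bg(x) - F_win(x)].

    Positive D+ means the window values sit above the background.  Returns
    ``(dplus, d_num)`` where ``d_num = dplus * m * n`` as an exact integer
    (ties resolved by the right-continuous ECDF convention).
    """
    w = np.sort(np.asarray(window_values, float))
    b = np.sort(np.asarray(background_values, float))
    m, n = len(w), len(b)
    if m == 0:
        raise ValueError("empty window")
    if n == 0:
        raise ValueError("empty background")
    pooled = np.concatenate([w, b])
    pooled.sort()
    i = np.searchsorted(w, pooled, side="right")  # window count <= x
    j = np.searchsorted(b, pooled, side="right")  # background count <= x
    num = j * m - i * n  # (F_bg - F_win) * m * n
    d_num = int(max(0, num.max()))
    return d_num / (m * n), d_num


def ks_exact_pvalue(d_num: int, m: int, n: int) -> float:
    """Exact P(D+ >= d) under the continuous null, d = d_num / (m*n).

    Dynamic programme over the lattice of interleavings: a path step takes
    either a window observation (i+1) or a background observation (j+1)
    with hypergeometric probability; mass is propagated only through states
    whose running ``j*m - i*n`` stays strictly below ``d_num``.
    """
    if d_num <= 0:
        return 1.0
    if d_num > m * n:
        return 0.0
    # prob[j] = probability of reaching (i, j) without touching the boundary
    prob = np.zeros(n + 1)
    prob[0] = 1.0
    total = m + n
    # i = 0 row: j*m must stay < d_num
    for j in range(1, n + 1):
        if j * m >= d_num:
            break
        prob[j] = prob[j - 1] * (n - j + 1) / (total - j + 1)
    for i in range(1, m + 1):
        new = np.zeros(n + 1)
        taken = i - 1  # steps consumed before adding this window obs, per j
        for j in range(0, n + 1):
            if j * m - i * n >= d_num:
                continue
            steps_before = (i - 1) + j
            acc = 0.0
            if prob[j] > 0:  # step from (i-1, j): take a window obs
                acc += prob[j] * (m - i + 1) / (total - steps_before)
            if j > 0 and new[j - 1] > 0:  # step from (i, j-1): background obs
                acc += new[j - 1] * (n - j + 1) / (total - (i + j - 1))
            new[j] = acc
        prob = new
    return float(min(max(1.0 - prob[n], 0.0), 1.0))


def ks_asymptotic_pvalue(dplus: float, m: int, n: int) -> float:
    return float(np.exp(-2.0 * m * n / (m + n) * dplus * dplus))


def ks_probe_score(
    window_values: Sequence[float],
    background_values: Sequence[float],
    direction: Literal["hyper", "hypo"] = "hyper",
    exact_limit: int = 10_000,
) -> tuple[float, float, float]:
    """Score one probe window against the array background.

    Returns ``(score, dplus, p_value)`` with ``score = -log10(p)``; the
    p-value comes from exact lattice enumeration when ``m * n`` is at most
    ``exact_limit`` and from the one-sided asymptotic formula otherwise.
    ``direction="hypo"`` negates all values (window stochastically smaller).
    """
    w = np.asarray(window_values, float)
    b = np.asarray(background_values, float)
    if direction == "hypo":
        w, b = -w, -b
    elif direction != "hyper":
        raise ValueError(f"direction must be 'hyper' or 'hypo', got {direction!r}")
    dplus, d_num = ks_dplus(w, b)
    m, n = len(w), len(b)
    if m * n <= exact_limit:
        p = ks_exact_pvalue(d_num, m, n)
    else:
        p = ks_asymptotic_pvalue(dplus, m, n)
    p = max(p, P_FLOOR)
    return -np.log10(p), dplus, p


# ---------------------------------------------------------------------------
# Whole-track scoring


def score_all_probes(
    probes: Sequence[ProbeLocus],
    values: pd.Series,
    sample_id: str = "",
    window_bp: int = 750,
    exact_limit: int = 10_000,
    background_cap: int = 50_000,
    seed: int = 0,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Score every probe in both directions against the rest of the array.

    The window holds all probes within ``window_bp / 2`` of the probe on its
    chromosome (the probe itself included); the background is every other
    autosomal probe on the array.  Arrays larger than ``background_cap``
    probes use a seeded subsample as background.  Returns a tidy frame with
    one row per (probe, direction).
    """
    plist = [p for p in probes if not autosomes_only or is_autosome(p.chromosome)]
    plist = sorted(plist, key=lambda p: (p.chromosome, p.position, p.probe_id))
    ids = [p.probe_id for p in plist]
    v = values.loc[ids].to_numpy(float)
    chroms = np.array([p.chromosome for p in plist])
    pos = np.array([p.position for p in plist])
    N = len(plist)
    # positions are sorted within each chromosome block; window search must
    # stay inside the block
    chrom_lo: dict[str, int] = {}
    chrom_hi: dict[str, int] = {}
    for t, c in enumerate(chroms):
        chrom_lo.setdefault(c, t)
        chrom_hi[c] = t + 1

    use_all = N <= background_cap
    if not use_all:
        keep = np.random.default_rng(seed).choice(N, size=background_cap, replace=False)
        bg_pool_mask = np.zeros(N, bool)
        bg_pool_mask[keep] = True
        logger.info("background subsampled to %d of %d probes", background_cap, N)
    else:
        bg_pool_mask = np.ones(N, bool)

    half = window_bp / 2.0
    rows = []
    for direction in ("hyper", "hypo"):
        vals = v if direction == "hyper" else -v
        order = np.argsort(vals, kind="mergesort")
        sorted_all = vals[order]
        pool_sorted = np.sort(vals[bg_pool_mask])
        for k in range(N):
            c = chroms[k]
            clo, chi = chrom_lo[c], chrom_hi[c]
            lo = clo + np.searchsorted(pos[clo:chi], pos[k] - half, side="left")
            hi = clo + np.searchsorted(pos[clo:chi], pos[k] + half, side="right")
            sel = list(range(lo, hi))
            w = np.sort(vals[sel])
            m = len(w)
            if use_all:
                # background = all values minus the window members
                grid = sorted_all
                cnt_all = np.searchsorted(sorted_all, grid, side="right")
                cw = np.searchsorted(w, grid, side="right")
                n_bg = N - m
                num = (cnt_all - cw) * m - cw * n_bg
                d_num = int(max(0, num.max()))
                dplus = d_num / (m * n_bg)
            else:
                bg = pool_sorted
                # remove window members that happen to be in the pool
                in_pool = [t for t in sel if bg_pool_mask[t]]
                if in_pool:
                    bg = bg.copy()
                    for t in in_pool:
                        idx = np.searchsorted(bg, vals[t], side="left")
                        bg = np.delete(bg, idx)
                dplus, d_num = ks_dplus(w, bg)
                n_bg = len(bg)
            if m * n_bg <= exact_limit:
                p = ks_exact_pvalue(d_num, m, n_bg)
            else:
                p = ks_asymptotic_pvalue(dplus, m, n_bg)
            p = max(p, P_FLOOR)
            rows.append(
                (sample_id, ids[k], c, int(pos[k]), direction, -np.log10(p), m)
            )
    return pd.DataFrame(
        rows,
        columns=["sample_id", "probe_id", "chromosome", "position", "direction", "score", "window_n"],
    )


# ---------------------------------------------------------------------------
# Peak calling and annotation


def find_peaks(
    scores: pd.DataFrame,
    min_probes: int = 2,
    score_threshold: float = 2.0,
) -> list[MethPeak]:
    """Maximal runs of consecutive probes with score >= threshold.

    ``scores`` must be ordered by (chromosome, position) within each
    direction (the :func:`score_all_probes` output is).  A run breaks at a
    chromosome change or any probe below the threshold; runs shorter than
    ``min_probes`` are discarded.
    """
    peaks: list[MethPeak] = []
    for (sample_id, direction), sub in scores.groupby(["sample_id", "direction"], sort=False):
        sub = sub.sort_values(["chromosome", "position"], kind="mergesort")
        run: list[tuple[str, str, int, float]] = []

        def flush() -> None:
            if len(run) >= min_probes:
                peaks.append(
                    MethPeak(
                        sample_id=sample_id,
                        chromosome=run[0][1],
                        start_bp=run[0][2],
                        end_bp=run[-1][2],
                        probe_ids=tuple(r[0] for r in run),
                        direction=direction,
                        mean_score=float(np.mean([r[3] for r in run])),
                    )
                )

        prev_chrom = None
        for r in sub.itertuples(index=False):
            if r.score >= score_threshold:
                if run and r.chromosome != prev_chrom:
                    flush()
                    run = []
                run.append((r.probe_id, r.chromosome, r.position, r.score))
                prev_chrom = r.chromosome
            else:
                flush()
                run = []
        flush()
    return peaks


def annotate_peaks(
    peaks: Sequence[MethPeak],
    windows: Sequence[PromoterWindow],
    probes: Sequence[ProbeLocus],
) -> pd.DataFrame:
    """Gene-level promoter methylation records from called peaks.

    A peak annotates every gene whose promoter window it overlaps by >= 1 bp.
    ``promoter_score`` averages the mean scores of all overlapping peaks of
    one direction; ``aberrant_fraction`` divides the window's probes that
    lie inside called peaks by all interrogated probes in the window.
    Windows with zero interrogated probes are suppressed with a warning.
    """
    by_chrom_pos: dict[str, np.ndarray] = {}
    by_chrom_ids: dict[str, list[str]] = {}
    for chrom in {p.chromosome for p in probes}:
        members = sorted(
            (p for p in probes if p.chromosome == chrom), key=lambda p: p.position
        )
        by_chrom_pos[chrom] = np.array([p.position for p in members])
        by_chrom_ids[chrom] = [p.probe_id for p in members]

    records: dict[tuple[str, str, str], dict] = {}
    for w in windows:
        if w.chromosome not in by_chrom_pos:
            continue
        pos = by_chrom_pos[w.chromosome]
        lo, hi = np.searchsorted(pos, [w.start, w.end], side="left")
        interrogated = set(by_chrom_ids[w.chromosome][lo:hi])
        if not interrogated:
            continue
        for pk in peaks:
            if pk.chromosome != w.chromosome:
                continue
            if pk.start_bp >= w.end or pk.end_bp < w.start:
                continue
            key = (pk.sample_id, w.gene_id, pk.direction)
            rec = records.setdefault(
                key,
                {
                    "peak_scores": [],
                    "peak_probes": set(),
                    "n_interrogated": len(interrogated),
                },
            )
            rec["peak_scores"].append(pk.mean_score)
            rec["peak_probes"].update(pid for pid in pk.probe_ids if pid in interrogated)

    suppressed = [
        w.gene_id
        for w in windows
        if w.chromosome in by_chrom_pos
        and not len(
            by_chrom_ids[w.chromosome][
                slice(*np.searchsorted(by_chrom_pos[w.chromosome], [w.start, w.end], side="left"))
            ]
        )
    ]
    if suppressed:
        logger.warning(
            "%d promoter window(s) contain no interrogated probes and are suppressed",
            len(suppressed),
        )

    rows = [
        {
            "sample_id": s,
            "gene_id": g,
            "direction": d,
            "promoter_score": float(np.mean(rec["peak_scores"])),
            "aberrant_fraction": len(rec["peak_probes"]) / rec["n_interrogated"],
            "n_peaks": len(rec["peak_scores"]),
        }
        for (s, g, d), rec in sorted(records.items())
    ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "gene_id", "direction", "promoter_score", "aberrant_fraction", "n_peaks"],
    )


def gene_meth_recurrence(
    records: pd.DataFrame,
    n_tumours: int,
    frequent_fraction: float = 0.6,
    min_fraction: float = 0.0,
) -> pd.DataFrame:
    """Per-gene, per-direction tumour counts and any/frequent flags.

    A gene qualifies as aberrant in a sample when it has at least one
    annotated peak of that direction (optionally also requiring
    ``aberrant_fraction >= min_fraction``).  The "frequent" flag is strict:
    count / n_tumours must exceed ``frequent_fraction``.
    """
    if records.empty:
        return pd.DataFrame(
            columns=["gene_id", "direction", "n_samples", "fraction", "any", "frequent"]
        )
    qual = records[records["aberrant_fraction"] >= min_fraction]
    counts = (
        qual.groupby(["gene_id", "direction"])["sample_id"].nunique().rename("n_samples")
    )
    out = counts.reset_index()
    out["fraction"] = out["n_samples"] / n_tumours
    out["any"] = out["n_samples"] >= 1
    out["frequent"] = out["fraction"] > frequent_fraction
    return out


def peaks_to_bed(peaks: Sequence[MethPeak]) -> pd.DataFrame:
    """BED-style frame (0-based start): chrom, start, end, name, score."""
    return pd.DataFrame(
        [
            {
                "chrom": p.chromosome,
                "start": p.start_bp,
                "end": p.end_bp + 1,
                "name": f"{p.sample_id}:{p.direction}",
                "score": round(p.mean_score, 4),
            }
            for p in peaks
        ]
    )
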