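"""Synthetic tumour/normal cohort generator with planted, recorded truth.

Emulates the three array layers of a small tumour-vs-normal profiling
study — copy-number probes at ~4 kb spacing, methylation probes at ~8 kb
spacing with dense promoter tiling, and a gene-level log2 expression
matrix — for a default cohort of 12 tumours and 9 normals.  Every planted
alteration (segmental gain/loss, promoter hyper/hypomethylation, expression
shift) is recorded in a :class:`CohortTruth`, so downstream calling stages
can be scored against known ground truth.

Signal model
------------
* aCGH log2 ratio (tumour vs pooled reference), probe ``p`` in tumour ``s``:
  sum of shifts of planted copy-number events assigned to ``s`` containing
  ``p``, plus ``gc_bias_amplitude * g(gc_p)`` with ``g`` a quadratic centred
  at GC 0.5, plus ``spatial_bias_amplitude * h(row, col)`` with ``h`` a
  one-cycle sinusoid over the array grid, plus N(0, ``noise_sd_cgh``).
* Methylation log2 ratio (tumour Cy3 vs matched-normal Cy5): planted
  promoter shift over the gene's promoter probes plus N(0, ``noise_sd_meth``).
* Expression: per-gene baseline + ``cn_expr_beta`` x (true CN shift) +
  ``meth_expr_beta`` x (true methylation shift) + direct planted expression
  effects + N(0, ``noise_sd_expr``).

Each (layer, sample) pair draws from its own pseudo-random stream derived
from the master seed, so enlarging the cohort never perturbs the data of
existing samples.

The methylation track carries, besides the ~8 kb backbone, a dense tile of
probes across each promoter (default 5 probes at 250 bp spacing around the
TSS).  This mirrors promoter-tiling array designs and is required for peak
calling to be achievable at all: with a 750 bp scoring window, a window
holding a single probe can never reach a score of 2 (the one-sided KS
p-value is bounded below by ~exp(-2) there).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneAnnotation,
    ProbeLocus,
    PromoterWindow,
    build_promoter_windows,
    read_gene_annotation,
    read_probe_track,
    sort_probes,
    write_gene_annotation,
    write_probe_track,
)

_LAYER_ASSIGN, _LAYER_CGH, _LAYER_METH, _LAYER_EXPR, _LAYER_GENOME = range(5)


def _rng(seed: int, layer: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), layer, index]))


@dataclass(frozen=True)
class CnaEvent:
    """A planted segmental copy-number event.

    ``log2_shift`` is the magnitude of the ratio shift; the sign follows
    ``direction`` (gain positive, loss negative).  ``recurrence_fraction``
    is the fraction of tumours carrying the event.
    """

    chromosome: str
    start: int
    end: int
    direction: Literal["gain", "loss"]
    log2_shift: float
    recurrence_fraction: float

    @property
    def signed_shift(self) -> float:
        return self.log2_shift if self.direction == "gain" else -self.log2_shift


@dataclass(frozen=True)
class MethEvent:
    """A planted promoter methylation event on one gene."""

    gene_id: str
    direction: Literal["hyper", "hypo"]
    log2_shift: float
    recurrence_fraction: float

    @property
    def signed_shift(self) -> float:
        return self.log2_shift if self.direction == "hyper" else -self.log2_shift


@dataclass(frozen=True)
class ExprEvent:
    """A direct planted expression effect (applied to all tumours)."""

    gene_id: str
    log2_fc: float


@dataclass
class CohortConfig:
    seed: int = 0
    n_tumours: int = 12
    n_normals: int = 9
    n_chromosomes: int = 4
    chrom_length_bp: int = 2_000_000
    cgh_spacing_bp: int = 4_000
    meth_spacing_bp: int = 8_000
    n_genes: int = 200
    probes_per_promoter: int = 5
    promoter_probe_spacing_bp: int = 250
    cna_events: list[CnaEvent] = field(default_factory=list)
    meth_events: list[MethEvent] = field(default_factory=list)
    expr_events: list[ExprEvent] = field(default_factory=list)
    cn_expr_beta: float = 1.0
    meth_expr_beta: float = -0.5
    noise_sd_cgh: float = 0.15
    noise_sd_meth: float = 0.2
    noise_sd_expr: float = 0.5
    gc_bias_amplitude: float = 0.0
    spatial_bias_amplitude: float = 0.0

    def __post_init__(self) -> None:
        for ev in list(self.cna_events) + list(self.meth_events):
            if not 0.0 <= ev.recurrence_fraction <= 1.0:
                raise ValueError("recurrence_fraction must be in [0,1]")
        if self.cgh_spacing_bp <= 0 or self.meth_spacing_bp <= 0:
            raise ValueError("probe spacings must be > 0")
        for sd in (self.noise_sd_cgh, self.noise_sd_meth, self.noise_sd_expr):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")


@dataclass
class CohortTruth:
    """Planted ground truth: which tumours carry which events, and the
    resulting expected expression group difference per gene."""

    cna_events: list[dict]
    meth_events: list[dict]
    expr_events: list[dict]
    expr_log2fc: dict[str, float]

    def to_dict(self) -> dict:
        return {
            "cna_events": self.cna_events,
            "meth_events": self.meth_events,
            "expr_events": self.expr_events,
            "expr_log2fc": self.expr_log2fc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortTruth":
        return cls(
            cna_events=d["cna_events"],
            meth_events=d["meth_events"],
            expr_events=d["expr_events"],
            expr_log2fc=d["expr_log2fc"],
        )


@dataclass
class Cohort:
    config: CohortConfig
    genes: list[GeneAnnotation]
    cgh_probes: list[ProbeLocus]
    cgh_ratios: pd.DataFrame  # probes x tumours
    meth_probes: list[ProbeLocus]
    meth_ratios: pd.DataFrame  # probes x tumours
    expression: pd.DataFrame  # genes x (tumours + normals)
    samples: pd.DataFrame  # sample_id, group
    truth: CohortTruth

    @property
    def tumour_ids(self) -> list[str]:
        return list(self.samples.loc[self.samples.group == "tumour", "sample_id"])

    @property
    def normal_ids(self) -> list[str]:
        return list(self.samples.loc[self.samples.group == "normal", "sample_id"])


def _build_genome(cfg: CohortConfig) -> list[GeneAnnotation]:
    """Evenly spaced gene bodies, alternating strand, TSS at the 5' end."""
    genes: list[GeneAnnotation] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    # leave headroom at both chromosome ends for promoter windows
    usable = cfg.chrom_length_bp - 20_000
    spacing = max(usable // max(per_chrom, 1), 12_000)
    body_len = min(spacing // 2, 20_000)
    idx = 0
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        for k in range(per_chrom):
            if idx >= cfg.n_genes:
                break
            start = 10_000 + k * spacing
            end = start + body_len
            if end + 10_000 > cfg.chrom_length_bp:
                break
            strand = "+" if idx % 2 == 0 else "-"
            tss = start if strand == "+" else end
            genes.append(
                GeneAnnotation(
                    gene_id=f"G{idx:04d}",
                    chromosome=chrom,
                    strand=strand,
                    tss_list=(tss,),
                    body_start=start,
                    body_end=end,
                )
            )
            idx += 1
    return genes


def _build_cgh_probes(cfg: CohortConfig) -> list[ProbeLocus]:
    rng = _rng(cfg.seed, _LAYER_GENOME, 0)
    probes: list[ProbeLocus] = []
    n_per_chrom = cfg.chrom_length_bp // cfg.cgh_spacing_bp
    total = n_per_chrom * cfg.n_chromosomes
    side = int(np.ceil(np.sqrt(total)))
    i = 0
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        for k in range(n_per_chrom):
            pos = k * cfg.cgh_spacing_bp + cfg.cgh_spacing_bp // 2
            gc = round(float(rng.uniform(0.3, 0.7)), 6)
            probes.append(
                ProbeLocus(
                    probe_id=f"CGH{i:06d}",
                    chromosome=chrom,
                    position=pos,
                    gc_fraction=gc,
                    array_row=i // side,
                    array_col=i % side,
                )
            )
            i += 1
    return probes


def _build_meth_probes(cfg: CohortConfig, genes: Sequence[GeneAnnotation]) -> list[ProbeLocus]:
    rng = _rng(cfg.seed, _LAYER_GENOME, 1)
    positions: dict[str, set[int]] = {str(c + 1): set() for c in range(cfg.n_chromosomes)}
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        for k in range(cfg.chrom_length_bp // cfg.meth_spacing_bp):
            positions[chrom].add(k * cfg.meth_spacing_bp + cfg.meth_spacing_bp // 2)
    half_tile = (cfg.probes_per_promoter - 1) // 2
    for g in genes:
        t = g.upstream_tss
        for j in range(cfg.probes_per_promoter):
            off = (j - half_tile) * cfg.promoter_probe_spacing_bp
            pos = t + off if g.strand == "+" else t - off
            if 0 <= pos < cfg.chrom_length_bp:
                positions[g.chromosome].add(pos)
    probes: list[ProbeLocus] = []
    i = 0
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        for pos in sorted(positions[chrom]):
            gc = round(float(rng.uniform(0.3, 0.7)), 6)
            probes.append(
                ProbeLocus(probe_id=f"M{i:06d}", chromosome=chrom, position=pos, gc_fraction=gc)
            )
            i += 1
    return probes


def _assign_tumours(
    rng: np.random.Generator, tumour_ids: Sequence[str], recurrence_fraction: float
) -> list[str]:
    n_carry = int(round(recurrence_fraction * len(tumour_ids)))
    chosen = rng.choice(len(tumour_ids), size=n_carry, replace=False)
    return sorted(tumour_ids[i] for i in chosen)


def gc_bias_curve(gc: np.ndarray) -> np.ndarray:
    """Smooth quadratic GC response, centred at GC 0.5, range ~[-1, 1]."""
    return 8.0 * (gc - 0.5) ** 2 - 1.0


def spatial_bias_surface(row: np.ndarray, col: np.ndarray, n_rows: int, n_cols: int) -> np.ndarray:
    """One-cycle sinusoidal surface over the array grid, range [-1, 1]."""
    return np.sin(2 * np.pi * row / max(n_rows, 1)) * np.cos(2 * np.pi * col / max(n_cols, 1))


def simulate_cohort(config: CohortConfig) -> Cohort:
    """Generate the full three-layer cohort for the configured study design."""
    cfg = config
    genes = _build_genome(cfg)
    gene_by_id = {g.gene_id: g for g in genes}
    for ev in cfg.meth_events:
        if ev.gene_id not in gene_by_id:
            raise ValueError(f"meth event gene {ev.gene_id!r} absent from annotation")
    for ev in cfg.expr_events:
        if ev.gene_id not in gene_by_id:
            raise ValueError(f"expr event gene {ev.gene_id!r} absent from annotation")
    chrom_set = {str(c + 1) for c in range(cfg.n_chromosomes)}
    for ev in cfg.cna_events:
        from .genome import normalize_chrom

        if normalize_chrom(ev.chromosome) not in chrom_set:
            raise ValueError(f"CNA event chromosome {ev.chromosome!r} outside genome")
        if not (0 <= ev.start < ev.end <= cfg.chrom_length_bp):
            raise ValueError(
                f"CNA event region [{ev.start}, {ev.end}) outside genome "
                f"(chromosome length {cfg.chrom_length_bp})"
            )

    tumour_ids = [f"T{i+1:02d}" for i in range(cfg.n_tumours)]
    normal_ids = [f"N{i+1:02d}" for i in range(cfg.n_normals)]
    samples = pd.DataFrame(
        {
            "sample_id": tumour_ids + normal_ids,
            "group": ["tumour"] * cfg.n_tumours + ["normal"] * cfg.n_normals,
        }
    )

    cgh_probes = _build_cgh_probes(cfg)
    meth_probes = _build_meth_probes(cfg, genes)
    windows = build_promoter_windows(
        genes, 5000, 1000, chrom_lengths={c: cfg.chrom_length_bp for c in chrom_set}
    )
    win_by_gene = {w.gene_id: w for w in windows}

    # --- event-to-tumour assignment (one stream per event list) ---
    cna_truth, meth_truth = [], []
    for j, ev in enumerate(cfg.cna_events):
        carriers = _assign_tumours(_rng(cfg.seed, _LAYER_ASSIGN, j), tumour_ids, ev.recurrence_fraction)
        d = asdict(ev)
        d["chromosome"] = str(ev.chromosome)
        d["samples"] = carriers
        cna_truth.append(d)
    for j, ev in enumerate(cfg.meth_events):
        carriers = _assign_tumours(
            _rng(cfg.seed, _LAYER_ASSIGN, 1000 + j), tumour_ids, ev.recurrence_fraction
        )
        d = asdict(ev)
        d["samples"] = carriers
        meth_truth.append(d)

    # --- aCGH layer ---
    cgh_pos = {c: np.array([p.position for p in cgh_probes if p.chromosome == c]) for c in chrom_set}
    cgh_ids_by_chrom = {c: [p.probe_id for p in cgh_probes if p.chromosome == c] for c in chrom_set}
    probe_index = {p.probe_id: i for i, p in enumerate(cgh_probes)}
    n_cgh = len(cgh_probes)
    gc = np.array([p.gc_fraction for p in cgh_probes])
    rows = np.array([p.array_row for p in cgh_probes])
    cols = np.array([p.array_col for p in cgh_probes])
    side = int(rows.max()) + 1 if n_cgh else 1
    bias = cfg.gc_bias_amplitude * gc_bias_curve(gc)
    bias = bias + cfg.spatial_bias_amplitude * spatial_bias_surface(rows, cols, side, side)

    cgh_mat = np.zeros((n_cgh, cfg.n_tumours))
    shift_by_sample = {s: np.zeros(n_cgh) for s in tumour_ids}
    from .genome import normalize_chrom

    for d in cna_truth:
        chrom = normalize_chrom(d["chromosome"])
        lo, hi = np.searchsorted(cgh_pos[chrom], [d["start"], d["end"]], side="left")
        ids = cgh_ids_by_chrom[chrom][lo:hi]
        sel = np.array([probe_index[i] for i in ids], dtype=int)
        sgn = d["log2_shift"] if d["direction"] == "gain" else -d["log2_shift"]
        for s in d["samples"]:
            shift_by_sample[s][sel] += sgn
    for si, s in enumerate(tumour_ids):
        noise = _rng(cfg.seed, _LAYER_CGH, si).normal(0.0, cfg.noise_sd_cgh, n_cgh) if cfg.noise_sd_cgh > 0 else 0.0
        cgh_mat[:, si] = shift_by_sample[s] + bias + noise
    cgh_ratios = pd.DataFrame(cgh_mat, index=[p.probe_id for p in cgh_probes], columns=tumour_ids)
    cgh_ratios.index.name = "probe_id"

    # --- methylation layer ---
    n_meth = len(meth_probes)
    meth_pos = {c: np.array([p.position for p in meth_probes if p.chromosome == c]) for c in chrom_set}
    meth_ids_by_chrom = {c: [p.probe_id for p in meth_probes if p.chromosome == c] for c in chrom_set}
    meth_index = {p.probe_id: i for i, p in enumerate(meth_probes)}
    meth_shift = {s: np.zeros(n_meth) for s in tumour_ids}
    for d in meth_truth:
        w = win_by_gene[d["gene_id"]]
        lo, hi = np.searchsorted(meth_pos[w.chromosome], [w.start, w.end], side="left")
        ids = meth_ids_by_chrom[w.chromosome][lo:hi]
        sel = np.array([meth_index[i] for i in ids], dtype=int)
        sgn = d["log2_shift"] if d["direction"] == "hyper" else -d["log2_shift"]
        for s in d["samples"]:
            meth_shift[s][sel] += sgn
    meth_mat = np.zeros((n_meth, cfg.n_tumours))
    for si, s in enumerate(tumour_ids):
        noise = _rng(cfg.seed, _LAYER_METH, si).normal(0.0, cfg.noise_sd_meth, n_meth) if cfg.noise_sd_meth > 0 else 0.0
        meth_mat[:, si] = meth_shift[s] + noise
    meth_ratios = pd.DataFrame(meth_mat, index=[p.probe_id for p in meth_probes], columns=tumour_ids)
    meth_ratios.index.name = "probe_id"

    # --- expression layer ---
    base_rng = _rng(cfg.seed, _LAYER_GENOME, 2)
    baseline = base_rng.uniform(6.0, 10.0, len(genes))
    gene_ids = [g.gene_id for g in genes]
    gene_pos_index = {gid: i for i, gid in enumerate(gene_ids)}
    # deterministic per-(gene, tumour) regulatory effect
    effect = {s: np.zeros(len(genes)) for s in tumour_ids}
    for d in cna_truth:
        chrom = normalize_chrom(d["chromosome"])
        sgn = d["log2_shift"] if d["direction"] == "gain" else -d["log2_shift"]
        hit = [
            gene_pos_index[g.gene_id]
            for g in genes
            if g.chromosome == chrom and g.body_start < d["end"] and g.body_end > d["start"]
        ]
        for s in d["samples"]:
            effect[s][hit] += cfg.cn_expr_beta * sgn
    for d in meth_truth:
        sgn = d["log2_shift"] if d["direction"] == "hyper" else -d["log2_shift"]
        gi = gene_pos_index[d["gene_id"]]
        for s in d["samples"]:
            effect[s][gi] += cfg.meth_expr_beta * sgn
    for ev in cfg.expr_events:
        gi = gene_pos_index[ev.gene_id]
        for s in tumour_ids:
            effect[s][gi] += ev.log2_fc

    all_ids = tumour_ids + normal_ids
    expr_mat = np.zeros((len(genes), len(all_ids)))
    for si, s in enumerate(all_ids):
        noise = (
            _rng(cfg.seed, _LAYER_EXPR, si).normal(0.0, cfg.noise_sd_expr, len(genes))
            if cfg.noise_sd_expr > 0
            else 0.0
        )
        expr_mat[:, si] = baseline + (effect[s] if s in effect else 0.0) + noise
    expression = pd.DataFrame(expr_mat, index=gene_ids, columns=all_ids)
    expression.index.name = "gene_id"

    expr_log2fc = {
        gid: float(np.mean([effect[s][gene_pos_index[gid]] for s in tumour_ids])) if tumour_ids else 0.0
        for gid in gene_ids
    }
    truth = CohortTruth(
        cna_events=cna_truth,
        meth_events=meth_truth,
        expr_events=[asdict(ev) for ev in cfg.expr_events],
        expr_log2fc=expr_log2fc,
    )
    return Cohort(
        config=cfg,
        genes=genes,
        cgh_probes=sort_probes(cgh_probes),
        cgh_ratios=cgh_ratios,
        meth_probes=sort_probes(meth_probes),
        meth_ratios=meth_ratios,
        expression=expression,
        samples=samples,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Disk round-trip

_FILES = {
    "annotation": "annotation.tsv",
    "cgh_probes": "cgh_probes.bed",
    "meth_probes": "meth_probes.bed",
    "cgh_ratios": "cgh_ratios.tsv",
    "meth_ratios": "meth_ratios.tsv",
    "expression": "expression.tsv",
    "samples": "samples.tsv",
    "truth": "truth.json",
}


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write all cohort layers to ``directory``; returns the file map."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {k: d / v for k, v in _FILES.items()}
    try:
        write_gene_annotation(cohort.genes, paths["annotation"])
        write_probe_track(cohort.cgh_probes, paths["cgh_probes"])
        write_probe_track(cohort.meth_probes, paths["meth_probes"])
        cohort.cgh_ratios.to_csv(paths["cgh_ratios"], sep="\t")
        cohort.meth_ratios.to_csv(paths["meth_ratios"], sep="\t")
        cohort.expression.to_csv(paths["expression"], sep="\t")
        cohort.samples.to_csv(paths["samples"], sep="\t", index=False)
        with open(paths["truth"], "w") as fh:
            json.dump(cohort.truth.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    except OSError as e:
        raise OSError(f"failed writing cohort file: {e.filename or directory}: {e}") from e
    return paths


def read_cohort(directory, config: CohortConfig | None = None) -> Cohort:
    d = Path(directory)
    genes = read_gene_annotation(d / _FILES["annotation"])
    cgh_probes = read_probe_track(d / _FILES["cgh_probes"])
    meth_probes = read_probe_track(d / _FILES["meth_probes"])
    cgh_ratios = pd.read_csv(d / _FILES["cgh_ratios"], sep="\t", index_col=0)
    meth_ratios = pd.read_csv(d / _FILES["meth_ratios"], sep="\t", index_col=0)
    expression = pd.read_csv(d / _FILES["expression"], sep="\t", index_col=0)
    samples = pd.read_csv(d / _FILES["samples"], sep="\t", dtype=str)
    with open(d / _FILES["truth"]) as fh:
        truth = CohortTruth.from_dict(json.load(fh))
    return Cohort(
        config=config if config is not None else CohortConfig(),
        genes=genes,
        cgh_probes=cgh_probes,
        meth_probes=meth_probes,
        cgh_ratios=cgh_ratios,
        meth_ratios=meth_ratios,
        expression=expression,
        samples=samples,
        truth=truth,
    )
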