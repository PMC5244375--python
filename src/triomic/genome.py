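"""Gene/TSS annotation, promoter windows, and probe-to-gene mapping.

Coordinate conventions
----------------------
All intervals are 0-based half-open internally.  BED-style output stays
0-based; human-readable tabular reports are converted to 1-based inclusive
at the writing stage.  Chromosome names are normalised on ingest:
case-insensitive, with an optional ``chr`` prefix stripped, so ``chr1``,
``Chr1`` and ``1`` all denote the same chromosome.

A probe's genomic anchor is its midpoint (the arrays use 50-mer probes;
the midpoint is the natural single-base summary of the hybridised span).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SEX_CHROMOSOMES = frozenset({"x", "y"})


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome label: lowercase, ``chr`` prefix stripped."""
    s = str(name).strip().lower()
    if s.startswith("chr"):
        s = s[3:]
    return s


def is_autosome(name: str) -> bool:
    return normalize_chrom(name) not in SEX_CHROMOSOMES


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with one or more transcription start sites.

    ``tss_list`` holds every annotated TSS; promoter construction picks the
    5'-most one in transcription orientation.  ``body_start``/``body_end``
    give the gene extent as a 0-based half-open interval.
    """

    gene_id: str
    chromosome: str
    strand: Literal["+", "-"]
    tss_list: tuple[int, ...]
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        object.__setattr__(self, "tss_list", tuple(int(t) for t in self.tss_list))
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: unknown strand symbol {self.strand!r}"
            )
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id!r}: empty tss_list")
        if not self.body_start < self.body_end:
            raise ValueError(
                f"gene {self.gene_id!r}: body_start must be < body_end "
                f"({self.body_start} >= {self.body_end})"
            )

    @property
    def upstream_tss(self) -> int:
        """The 5'-most TSS in transcription orientation.

        On the + strand that is the smallest coordinate; on the − strand the
        largest ("upstream" is strand-relative in a promoter context).
        """
        return min(self.tss_list) if self.strand == "+" else max(self.tss_list)


@dataclass(frozen=True)
class PromoterWindow:
    """Strand-oriented promoter interval around a gene's representative TSS."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    source_tss: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        if not self.start < self.end:
            raise ValueError(f"window {self.gene_id!r}: empty interval")


@dataclass(frozen=True)
class ProbeLocus:
    """A single array probe anchored at its midpoint position."""

    probe_id: str
    chromosome: str
    position: int
    gc_fraction: float = 0.5
    array_row: int | None = None
    array_col: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosome", normalize_chrom(self.chromosome))
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError(
                f"probe {self.probe_id!r}: gc_fraction {self.gc_fraction} not in [0,1]"
            )


def build_promoter_windows(
    genes: Sequence[GeneAnnotation],
    upstream_bp: int = 5000,
    downstream_bp: int = 1000,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[PromoterWindow]:
    """One promoter window per gene around its most-upstream TSS.

    The window spans ``upstream_bp`` 5' of the TSS and ``downstream_bp`` 3'
    of it, oriented by strand: for a + strand gene with TSS ``t`` the window
    is ``[t − upstream, t + downstream)``; for − strand ``[t − downstream,
    t + upstream)``.  For multi-TSS genes the 5'-most TSS in transcription
    orientation is used.  Windows are clipped at position 0 and, when
    ``chrom_lengths`` is given, at the chromosome end (clipping is logged).
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("upstream_bp and downstream_bp must be >= 0")
    windows: list[PromoterWindow] = []
    for g in genes:
        t = g.upstream_tss
        if g.strand == "+":
            start, end = t - upstream_bp, t + downstream_bp
        else:
            start, end = t - downstream_bp, t + upstream_bp
        clipped_start = max(start, 0)
        clipped_end = end
        if chrom_lengths is not None and g.chromosome in chrom_lengths:
            clipped_end = min(end, chrom_lengths[g.chromosome])
        if (clipped_start, clipped_end) != (start, end):
            logger.warning(
                "promoter window for %s clipped to chromosome bounds "
                "[%d, %d) -> [%d, %d)", g.gene_id, start, end,
                clipped_start, clipped_end,
            )
        windows.append(
            PromoterWindow(g.gene_id, g.chromosome, clipped_start, clipped_end, t)
        )
    return windows


def _gene_intervals(
    genes: Sequence[GeneAnnotation],
    mode: str,
    promoter_windows: Sequence[PromoterWindow] | None,
) -> list[tuple[str, str, int, int]]:
    if mode == "body":
        return [(g.gene_id, g.chromosome, g.body_start, g.body_end) for g in genes]
    if mode == "promoter":
        wins = promoter_windows
        if wins is None:
            wins = build_promoter_windows(genes)
        return [(w.gene_id, w.chromosome, w.start, w.end) for w in wins]
    raise ValueError(f"mode must be 'body' or 'promoter', got {mode!r}")


def map_probes_to_genes(
    probes: Sequence[ProbeLocus],
    genes: Sequence[GeneAnnotation],
    mode: Literal["body", "promoter"] = "body",
    promoter_windows: Sequence[PromoterWindow] | None = None,
) -> tuple[dict[str, list[str]], set[str]]:
    """Map probes into gene bodies or promoter windows by containment.

    Returns ``(gene_id -> [probe_id, ...], intergenic probe-id set)``.  A
    probe maps to every overlapping gene (no tie-breaking — gene-level
    recurrence is reported per gene, so multi-assignment is the neutral
    choice); probes contained by no interval are intergenic.  Probes on
    chromosomes absent from the annotation are intergenic with a warning.
    """
    intervals = _gene_intervals(genes, mode, promoter_windows)
    by_chrom_pos: dict[str, np.ndarray] = {}
    by_chrom_ids: dict[str, list[str]] = {}
    for chrom in {p.chromosome for p in probes}:
        members = [p for p in probes if p.chromosome == chrom]
        members.sort(key=lambda p: (p.position, p.probe_id))
        by_chrom_pos[chrom] = np.array([p.position for p in members])
        by_chrom_ids[chrom] = [p.probe_id for p in members]

    annotated_chroms = {c for _, c, _, _ in intervals}
    for chrom in by_chrom_pos:
        if chrom not in annotated_chroms:
            logger.warning(
                "chromosome %r present in probes but absent from annotation; "
                "its probes are treated as intergenic", chrom,
            )

    mapping: dict[str, list[str]] = {}
    mapped: set[str] = set()
    for gene_id, chrom, start, end in intervals:
        hits: list[str] = []
        if chrom in by_chrom_pos:
            pos = by_chrom_pos[chrom]
            lo, hi = np.searchsorted(pos, [start, end], side="left")
            hits = by_chrom_ids[chrom][lo:hi]
        mapping.setdefault(gene_id, []).extend(hits)
        mapped.update(hits)
    intergenic = {p.probe_id for p in probes} - mapped
    return mapping, intergenic


def filter_autosomes(items: Iterable) -> list:
    """Drop every item located on chromosome X or Y.

    Works on any collection of objects with a ``chromosome`` attribute
    (genes, probes, windows, segments).  The number removed is logged.
    """
    items = list(items)
    kept = [it for it in items if is_autosome(it.chromosome)]
    removed = len(items) - len(kept)
    if removed:
        logger.info("filter_autosomes: removed %d item(s) on X/Y", removed)
    return kept


def filter_autosomes_df(df: pd.DataFrame, chrom_col: str = "chromosome") -> pd.DataFrame:
    """DataFrame variant of :func:`filter_autosomes`."""
    mask = df[chrom_col].map(is_autosome)
    removed = int((~mask).sum())
    if removed:
        logger.info("filter_autosomes: removed %d row(s) on X/Y", removed)
    return df.loc[mask]


# ---------------------------------------------------------------------------
# Readers / writers


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Read a refFlat-like TSV: gene_id, chrom, strand, txStart, txEnd, tss_list.

    ``tss_list`` is comma-separated genomic positions; when the column is
    missing, txStart (+ strand) or txEnd (− strand) supplies the single TSS.
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "strand", "txStart", "txEnd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path}: missing columns {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        if "tss_list" in df.columns and not pd.isna(row.tss_list):
            tss = tuple(int(x) for x in str(row.tss_list).split(","))
        else:
            tss = (int(row.txStart) if row.strand == "+" else int(row.txEnd),)
        genes.append(
            GeneAnnotation(
                gene_id=str(row.gene_id),
                chromosome=str(row.chrom),
                strand=row.strand,
                tss_list=tss,
                body_start=int(row.txStart),
                body_end=int(row.txEnd),
            )
        )
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chromosome for g in genes],
            "strand": [g.strand for g in genes],
            "txStart": [g.body_start for g in genes],
            "txEnd": [g.body_end for g in genes],
            "tss_list": [",".join(map(str, g.tss_list)) for g in genes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_gene_annotation_gff3(path) -> list[GeneAnnotation]:
    """Read gene models from GFF3: gene features define bodies, each
    transcript/mRNA start (strand-aware) contributes a TSS to its parent."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        tss: list[int] = []
        for tx in db.children(g, level=1):
            if tx.featuretype not in ("transcript", "mRNA"):
                continue
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            tss.append(tx.start - 1 if g.strand == "+" else tx.end)
        if not tss:
            tss = [g.start - 1 if g.strand == "+" else g.end]
        gene_id = g.attributes.get("ID", [g.id])[0]
        genes.append(
            GeneAnnotation(
                gene_id=gene_id,
                chromosome=g.seqid,
                strand=g.strand,
                tss_list=tuple(sorted(set(tss))),
                body_start=g.start - 1,
                body_end=g.end,
            )
        )
    return genes


def read_probe_track(path) -> list[ProbeLocus]:
    """Read a BED-like probe track: chrom, start, end, probe_id,
    gc_fraction[, row, col].  Probe position is the interval midpoint."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "probe_id", "gc_fraction", "row", "col"],
        dtype={"chrom": str, "probe_id": str},
    )
    probes = []
    for r in df.itertuples(index=False):
        has_grid = not (pd.isna(r.row) or pd.isna(r.col))
        probes.append(
            ProbeLocus(
                probe_id=str(r.probe_id),
                chromosome=str(r.chrom),
                position=(int(r.start) + int(r.end)) // 2,
                gc_fraction=0.5 if pd.isna(r.gc_fraction) else float(r.gc_fraction),
                array_row=int(r.row) if has_grid else None,
                array_col=int(r.col) if has_grid else None,
            )
        )
    return probes


def write_probe_track(probes: Sequence[ProbeLocus], path, probe_len: int = 50) -> None:
    half = probe_len // 2
    rows = []
    for p in probes:
        rows.append(
            (
                p.chromosome,
                max(p.position - half, 0),
                p.position + (probe_len - half),
                p.probe_id,
                round(p.gc_fraction, 6),
                "" if p.array_row is None else p.array_row,
                "" if p.array_col is None else p.array_col,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def sort_probes(probes: Sequence[ProbeLocus]) -> list[ProbeLocus]:
    return sorted(probes, key=lambda p: (p.chromosome, p.position, p.probe_id))
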