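"""Gene-level integration of expression, copy-number and methylation calls.

The three per-gene layers are outer-joined over the annotation gene set
into a :class:`GeneStatusTable`-style frame and intersected into the
concordance categories of an integrative tumour analysis:

* overexpressed & copy-number gained, under-expressed & lost,
* overexpressed & promoter-hypomethylated, under-expressed & hypermethylated,
* the two triple overlaps (expression + CN + methylation, concordant),
* union counts for "expression associated with CN or methylation" and
  "associated with both".

A gene that was never assessed in a layer (absent from that layer's input)
is excluded from intersections involving that layer rather than counted as
negative, so missing data never deflates concordance counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .genome import GeneAnnotation

logger = logging.getLogger(__name__)

PAIR_CATEGORIES = ("up_gain", "down_loss", "up_hypo", "down_hyper")
TRIPLE_CATEGORIES = ("up_gain_hypo", "down_loss_hyper")


@dataclass
class IntegrationSummary:
    counts: dict[str, int]
    gene_lists: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {"counts": self.counts, "gene_lists": self.gene_lists}


def build_gene_status_table(
    genes: Sequence[GeneAnnotation] | Sequence[str],
    de_results: pd.DataFrame | None,
    cn_recurrence: pd.DataFrame | None,
    meth_recurrence: pd.DataFrame | None,
    meth_rule: Literal["any", "frequent"] = "any",
) -> pd.DataFrame:
    """Outer-join the three per-gene layers over the annotation gene set.

    Parameters
    ----------
    genes
        the annotation (GeneAnnotation objects or bare gene ids); defines
        the row universe.
    de_results
        DE table indexed by gene_id with a ``status`` column (up/down/none).
    cn_recurrence
        gene recurrence table indexed by gene_id with boolean ``amplified``
        / ``deleted`` columns (thresholds already applied upstream).
    meth_recurrence
        tidy frame from :func:`triomic.methylation.gene_meth_recurrence`
        with gene_id, direction and any/frequent flags; ``meth_rule`` picks
        which flag qualifies a gene.

    Rows are ordered lexicographically by gene_id.  Layer absence is marked
    by the per-layer ``*_assessed`` flag; duplicate gene ids within a layer
    are rejected.
    """
    gene_ids = sorted(
        g.gene_id if isinstance(g, GeneAnnotation) else str(g) for g in genes
    )
    table = pd.DataFrame(index=pd.Index(gene_ids, name="gene_id"))
    table["de_status"] = "none"
    table["de_assessed"] = False
    table["cn_amplified"] = False
    table["cn_deleted"] = False
    table["cn_gain_fraction"] = np.nan
    table["cn_loss_fraction"] = np.nan
    table["cn_assessed"] = False
    table["meth_hyper"] = False
    table["meth_hypo"] = False
    table["meth_assessed"] = False

    if de_results is not None and len(de_results):
        dup = de_results.index[de_results.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate gene_ids in DE layer: {dup}")
        common = table.index.intersection(de_results.index)
        table.loc[common, "de_status"] = de_results.loc[common, "status"]
        table.loc[common, "de_assessed"] = True

    if cn_recurrence is not None and len(cn_recurrence):
        dup = cn_recurrence.index[cn_recurrence.index.duplicated()].unique().tolist()
        if dup:
            raise ValueError(f"duplicate gene_ids in CN layer: {dup}")
        common = table.index.intersection(cn_recurrence.index)
        table.loc[common, "cn_amplified"] = cn_recurrence.loc[common, "amplified"]
        table.loc[common, "cn_deleted"] = cn_recurrence.loc[common, "deleted"]
        if "gain_fraction" in cn_recurrence.columns:
            table.loc[common, "cn_gain_fraction"] = cn_recurrence.loc[common, "gain_fraction"]
            table.loc[common, "cn_loss_fraction"] = cn_recurrence.loc[common, "loss_fraction"]
        table.loc[common, "cn_assessed"] = True

    if meth_recurrence is not None and len(meth_recurrence):
        flag = "any" if meth_rule == "any" else "frequent"
        dup = meth_recurrence.duplicated(subset=["gene_id", "direction"])
        if dup.any():
            raise ValueError(
                "duplicate (gene_id, direction) rows in methylation layer: "
                f"{meth_recurrence.loc[dup, 'gene_id'].unique().tolist()}"
            )
        for direction, col in (("hyper", "meth_hyper"), ("hypo", "meth_hypo")):
            sub = meth_recurrence[
                (meth_recurrence["direction"] == direction) & meth_recurrence[flag]
            ]
            hits = table.index.intersection(sub["gene_id"])
            table.loc[hits, col] = True
        # methylation was assessed genome-wide whenever the layer was supplied
        table["meth_assessed"] = True

    return table


def integrate(table: pd.DataFrame) -> IntegrationSummary:
    """Compute all Venn-category counts and sorted gene lists.

    Genes not assessed in a layer are excluded from intersections that
    involve that layer.  Union counts obey inclusion–exclusion by
    construction (they are computed as real set unions).
    """
    de_ok = table["de_assessed"]
    cn_ok = table["cn_assessed"]
    meth_ok = table["meth_assessed"]
    up = de_ok & (table["de_status"] == "up")
    down = de_ok & (table["de_status"] == "down")
    gain = cn_ok & table["cn_amplified"]
    loss = cn_ok & table["cn_deleted"]
    hyper = meth_ok & table["meth_hyper"]
    hypo = meth_ok & table["meth_hypo"]

    sets: dict[str, set[str]] = {
        "up_gain": set(table.index[up & gain]),
        "down_loss": set(table.index[down & loss]),
        "up_hypo": set(table.index[up & hypo]),
        "down_hyper": set(table.index[down & hyper]),
        "up_gain_hypo": set(table.index[up & gain & hypo]),
        "down_loss_hyper": set(table.index[down & loss & hyper]),
    }
    union_any = set().union(*(sets[c] for c in PAIR_CATEGORIES))
    union_both = sets["up_gain_hypo"] | sets["down_loss_hyper"]
    counts = {c: len(sets[c]) for c in PAIR_CATEGORIES + TRIPLE_CATEGORIES}
    counts["expression_with_cn_or_meth"] = len(union_any)
    counts["expression_with_cn_and_meth"] = len(union_both)
    gene_lists = {c: sorted(sets[c]) for c in sets}
    gene_lists["expression_with_cn_or_meth"] = sorted(union_any)
    gene_lists["expression_with_cn_and_meth"] = sorted(union_both)
    return IntegrationSummary(counts=counts, gene_lists=gene_lists)


def summarize_percentages(
    numerators: int | Sequence[int],
    denominators: int | Sequence[int],
    rounding: Literal["integer", "one_decimal"] = "integer",
) -> str | list[str]:
    """Format count/total quotients the way tumour-profiling reports do.

    ``integer`` style gives probe-level summaries like ``"92%"``;
    ``one_decimal`` gives gene-frequency style like ``"41.7%, 5/12"``.
    Scalars in, scalar out; sequences in, list out.
    """
    scalar = np.isscalar(numerators)
    nums = [numerators] if scalar else list(numerators)
    dens = [denominators] if scalar else list(denominators)
    out = []
    for num, den in zip(nums, dens):
        if den <= 0:
            raise ValueError("denominator must be > 0")
        pct = 100.0 * num / den
        if rounding == "integer":
            out.append(f"{pct:.0f}%")
        elif rounding == "one_decimal":
            out.append(f"{pct:.1f}%, {num}/{den}")
        else:
            raise ValueError(f"unknown rounding style {rounding!r}")
    return out[0] if scalar else out


# ---------------------------------------------------------------------------
# End-to-end pipeline


def run_pipeline(
    config: Mapping | None = None,
    out_dir: str | Path = "pipeline_out",
    cohort=None,
    seed: int | None = None,
) -> dict:
    """Execute simulate (optional) → DE → CNV → methylation → integration.

    ``config`` sections (all optional): ``simulate`` (CohortConfig fields
    plus ``cna_events`` / ``meth_events`` / ``expr_events`` as dicts),
    ``de`` (p_threshold, fc_threshold, gate), ``cnv`` (alpha, n_perm,
    min_width, k, mad_floor, frequency_cutoff, normalize, map_mode),
    ``meth`` (window_bp, min_probes, score_threshold, frequent_fraction,
    min_fraction), ``integration`` (meth_rule).  A prebuilt ``cohort``
    bypasses simulation.  Writes all stage tables plus ``summary.json``
    under ``out_dir`` and returns the summary dict; identical config+seed
    yields byte-identical summary JSON.
    """
    from .simulate import CnaEvent, CohortConfig, ExprEvent, MethEvent, simulate_cohort, write_cohort
    from . import cnv as cnvmod
    from . import methylation as methmod
    from .expression import run_de
    from .genome import build_promoter_windows, filter_autosomes, map_probes_to_genes

    config = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim_cfg_dict = dict(config.get("simulate", {}))
    if seed is not None:
        sim_cfg_dict["seed"] = seed
    if cohort is None:
        sim_cfg_dict["cna_events"] = [
            CnaEvent(**e) if not isinstance(e, CnaEvent) else e
            for e in sim_cfg_dict.get("cna_events", [])
        ]
        sim_cfg_dict["meth_events"] = [
            MethEvent(**e) if not isinstance(e, MethEvent) else e
            for e in sim_cfg_dict.get("meth_events", [])
        ]
        sim_cfg_dict["expr_events"] = [
            ExprEvent(**e) if not isinstance(e, ExprEvent) else e
            for e in sim_cfg_dict.get("expr_events", [])
        ]
        cohort_cfg = CohortConfig(**sim_cfg_dict)
        try:
            cohort = simulate_cohort(cohort_cfg)
        except Exception as e:
            raise RuntimeError(f"stage 'simulate' failed: {e}") from e
        write_cohort(cohort, out / "cohort")
    run_seed = cohort.config.seed if seed is None else seed

    de_cfg = dict(config.get("de", {}))
    cnv_cfg = dict(config.get("cnv", {}))
    meth_cfg = dict(config.get("meth", {}))
    int_cfg = dict(config.get("integration", {}))

    # --- expression DE ---
    try:
        de_table = run_de(
            cohort.expression,
            cohort.samples,
            p_threshold=de_cfg.get("p_threshold", 0.05),
            fc_threshold=de_cfg.get("fc_threshold", 2.0),
            gate=de_cfg.get("gate", "q"),
        )
    except Exception as e:
        raise RuntimeError(f"stage 'de' failed: {e}") from e
    de_table.to_csv(out / "de_genes.tsv", sep="\t")

    # --- copy number ---
    try:
        auto_probes = filter_autosomes(cohort.cgh_probes)
        seg_all, status_cols = [], {}
        for si, s in enumerate(cohort.tumour_ids):
            segs, noise, status = cnvmod.segment_sample(
                cohort.cgh_ratios[s],
                auto_probes,
                sample_id=s,
                alpha=cnv_cfg.get("alpha", 0.01),
                n_perm=cnv_cfg.get("n_perm", 1000),
                min_width=cnv_cfg.get("min_width", 2),
                seed=(run_seed * 1009 + si) % (2**31),
                normalize=cnv_cfg.get("normalize", False),
                k=cnv_cfg.get("k", 2.0),
                mad_floor=cnv_cfg.get("mad_floor", 0.01),
            )
            seg_all.extend(segs)
            status_cols[s] = status
        probe_status = pd.DataFrame(status_cols)
        cutoff = cnv_cfg.get("frequency_cutoff", 1.0 / 3.0)
        freqs = cnvmod.compute_cn_frequencies(probe_status, cutoff)
        gene_map, intergenic = map_probes_to_genes(
            auto_probes, cohort.genes, mode=cnv_cfg.get("map_mode", "body")
        )
        gene_status, cn_rec, no_probe_genes = cnvmod.gene_cn_status(
            probe_status, gene_map, intergenic, cutoff
        )
    except Exception as e:
        raise RuntimeError(f"stage 'cnv' failed: {e}") from e
    cnvmod.segments_to_frame(seg_all).to_csv(out / "segments.tsv", sep="\t", index=False)
    freqs.to_csv(out / "cn_probe_frequencies.tsv", sep="\t")
    cn_rec.to_csv(out / "cn_genes.tsv", sep="\t")

    # --- methylation ---
    try:
        auto_meth = filter_autosomes(cohort.meth_probes)
        windows = build_promoter_windows(filter_autosomes(cohort.genes))
        score_frames, peaks = [], []
        for si, s in enumerate(cohort.tumour_ids):
            sc = methmod.score_all_probes(
                auto_meth,
                cohort.meth_ratios[s],
                sample_id=s,
                window_bp=meth_cfg.get("window_bp", 750),
                seed=(run_seed * 2003 + si) % (2**31),
            )
            score_frames.append(sc)
            peaks.extend(
                methmod.find_peaks(
                    sc,
                    min_probes=meth_cfg.get("min_probes", 2),
                    score_threshold=meth_cfg.get("score_threshold", 2.0),
                )
            )
        gene_meth = methmod.annotate_peaks(peaks, windows, auto_meth)
        meth_rec = methmod.gene_meth_recurrence(
            gene_meth,
            n_tumours=len(cohort.tumour_ids),
            frequent_fraction=meth_cfg.get("frequent_fraction", 0.6),
            min_fraction=meth_cfg.get("min_fraction", 0.0),
        )
    except Exception as e:
        raise RuntimeError(f"stage 'meth' failed: {e}") from e
    methmod.peaks_to_bed(peaks).to_csv(out / "meth_peaks.bed", sep="\t", index=False, header=False)
    gene_meth.to_csv(out / "meth_genes.tsv", sep="\t", index=False)
    meth_rec.to_csv(out / "meth_recurrence.tsv", sep="\t", index=False)

    # --- integration ---
    try:
        table = build_gene_status_table(
            cohort.genes,
            de_table,
            cn_rec,
            meth_rec,
            meth_rule=int_cfg.get("meth_rule", "any"),
        )
        summary = integrate(table)
    except Exception as e:
        raise RuntimeError(f"stage 'integrate' failed: {e}") from e
    table.to_csv(out / "gene_status_table.tsv", sep="\t")
    for cat, genes_list in summary.gene_lists.items():
        pd.Series(genes_list, name="gene_id").to_csv(
            out / f"category_{cat}.tsv", sep="\t", index=False
        )

    payload = {
        "counts": summary.counts,
        "de_summary": {
            "n_up": int((de_table["status"] == "up").sum()),
            "n_down": int((de_table["status"] == "down").sum()),
        },
        "cn_summary": {
            "n_amplified_genes": int(cn_rec["amplified"].sum()),
            "n_deleted_genes": int(cn_rec["deleted"].sum()),
            "n_intergenic_probes": len(intergenic),
            "n_genes_without_probes": len(no_probe_genes),
        },
        "meth_summary": {
            "n_genes_hyper_any": int(
                ((meth_rec["direction"] == "hyper") & meth_rec["any"]).sum()
            ),
            "n_genes_hypo_any": int(
                ((meth_rec["direction"] == "hypo") & meth_rec["any"]).sum()
            ),
            "n_peaks": len(peaks),
        },
        "thresholds": {
            "de": {
                "p_threshold": de_cfg.get("p_threshold", 0.05),
                "fc_threshold": de_cfg.get("fc_threshold", 2.0),
                "gate": de_cfg.get("gate", "q"),
            },
            "cnv": {
                "alpha": cnv_cfg.get("alpha", 0.01),
                "n_perm": cnv_cfg.get("n_perm", 1000),
                "k": cnv_cfg.get("k", 2.0),
                "frequency_cutoff": cnv_cfg.get("frequency_cutoff", 1.0 / 3.0),
            },
            "meth": {
                "window_bp": meth_cfg.get("window_bp", 750),
                "min_probes": meth_cfg.get("min_probes", 2),
                "score_threshold": meth_cfg.get("score_threshold", 2.0),
                "frequent_fraction": meth_cfg.get("frequent_fraction", 0.6),
                "meth_rule": int_cfg.get("meth_rule", "any"),
            },
        },
        "seed": run_seed,
        "versions": {"triomic": __version__},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return payload
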