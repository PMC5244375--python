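"""Full three-layer pipeline on a planted concordant cohort.

Simulates 12 tumours vs 9 normals where genes G0005/G0006 are gained +
promoter-hypomethylated + overexpressed and G0035/G0036 are lost +
hypermethylated + under-expressed, runs DE, CNV and methylation calling,
and integrates the per-gene calls into Venn categories.  A perfect run
recovers exactly the four planted genes in the two triple categories.
"""

import json
import tempfile

from triomic.integrate import run_pipeline

config = {
    "simulate": dict(
        n_chromosomes=2,
        chrom_length_bp=1_200_000,
        n_genes=60,
        cna_events=[
            dict(chromosome="1", start=200_000, end=360_000, direction="gain",
                 log2_shift=0.58, recurrence_fraction=0.5),
            dict(chromosome="2", start=200_000, end=360_000, direction="loss",
                 log2_shift=0.58, recurrence_fraction=0.5),
        ],
        meth_events=[
            dict(gene_id="G0005", direction="hypo", log2_shift=2.0, recurrence_fraction=2 / 3),
            dict(gene_id="G0006", direction="hypo", log2_shift=2.0, recurrence_fraction=2 / 3),
            dict(gene_id="G0035", direction="hyper", log2_shift=2.0, recurrence_fraction=2 / 3),
            dict(gene_id="G0036", direction="hyper", log2_shift=2.0, recurrence_fraction=2 / 3),
        ],
        expr_events=[
            dict(gene_id="G0005", log2_fc=1.3),
            dict(gene_id="G0006", log2_fc=1.3),
            dict(gene_id="G0035", log2_fc=-1.3),
            dict(gene_id="G0036", log2_fc=-1.3),
        ],
    ),
    "cnv": dict(n_perm=200),
}

with tempfile.TemporaryDirectory() as out:
    summary = run_pipeline(config, out_dir=out, seed=11)

print(json.dumps(summary["counts"], indent=1))
# up_gain_hypo / down_loss_hyper = 2 each means all four planted
# triple-concordant genes were recovered with no spurious calls
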