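import numpy as np
import pytest

from triomic.genome import GeneAnnotation, ProbeLocus


def make_gene(gene_id="G1", chrom="1", strand="+", tss=(10_000,), start=10_000, end=30_000):
    return GeneAnnotation(
        gene_id=gene_id, chromosome=chrom, strand=strand,
        tss_list=tuple(tss), body_start=start, body_end=end,
    )


def make_probes(positions, chrom="1", prefix="P", gc=0.5):
    return [
        ProbeLocus(probe_id=f"{prefix}{i}", chromosome=chrom, position=int(p), gc_fraction=gc)
        for i, p in enumerate(positions)
    ]


def concordant_cohort_config(seed: int) -> dict:
    """Planted three-layer concordant design: two genes gained + promoter
    hypomethylated + overexpressed, two genes lost + hypermethylated +
    under-expressed, at module-default noise levels (12 tumours vs 9
    normals)."""
    return {
        "simulate": dict(
            seed=seed,
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


CONCORDANT_TRUTH = {
    "up_gain_hypo": ["G0005", "G0006"],
    "down_loss_hyper": ["G0035", "G0036"],
}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260921)
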