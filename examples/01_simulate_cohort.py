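"""Generate a synthetic tumour/normal cohort with planted ground truth.

Builds a 12-tumour / 9-normal cohort on a small two-chromosome genome with
one recurrent copy-number gain and one recurrently hypermethylated
promoter, then prints what was planted and where.  The truth record is
what downstream examples score themselves against.
"""

from triomic.simulate import CnaEvent, CohortConfig, MethEvent, simulate_cohort

cfg = CohortConfig(
    seed=1,
    n_chromosomes=2,
    chrom_length_bp=1_000_000,
    n_genes=50,
    cna_events=[CnaEvent("1", 200_000, 400_000, "gain", 0.58, recurrence_fraction=0.5)],
    meth_events=[MethEvent("G0030", "hyper", 2.0, recurrence_fraction=0.75)],
)
cohort = simulate_cohort(cfg)

print(f"genes: {len(cohort.genes)}  aCGH probes: {len(cohort.cgh_probes)}  "
      f"methylation probes: {len(cohort.meth_probes)}")
print(f"expression matrix: {cohort.expression.shape[0]} genes x "
      f"{cohort.expression.shape[1]} samples")
ev = cohort.truth.cna_events[0]
print(f"planted gain chr{ev['chromosome']}:{ev['start']}-{ev['end']} "
      f"(log2 +{ev['log2_shift']}) carried by {len(ev['samples'])}/12 tumours: "
      f"{','.join(ev['samples'])}")
me = cohort.truth.meth_events[0]
print(f"planted promoter hypermethylation on {me['gene_id']} in "
      f"{len(me['samples'])}/12 tumours")
# the recurrence fractions above fix how many tumours carry each event;
# the specific carriers are chosen by the seeded generator
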