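"""Promoter methylation peak calling with the windowed one-sided KS score.

A 400-probe methylation track (8 kb backbone plus a 5-probe tile across one
promoter) with the tile shifted +2 in the tumour-vs-normal log2 ratio.
Each probe's 750 bp window is tested against the rest of the array; runs of
>= 2 probes with score >= 2 become peaks, which are then annotated to
promoter windows (5 kb upstream / 1 kb downstream of the TSS).
"""

import numpy as np
import pandas as pd

from triomic.genome import PromoterWindow, ProbeLocus
from triomic.methylation import annotate_peaks, find_peaks, score_all_probes

rng = np.random.default_rng(3)
backbone = [int(p) for p in np.arange(395) * 8000]
tile = [1_200_000 + 250 * k for k in range(5)]  # dense tile at the promoter
positions = sorted(set(backbone + tile))
probes = [ProbeLocus(f"m{i:03d}", "1", p, 0.5) for i, p in enumerate(positions)]

values = pd.Series(rng.normal(0, 0.2, len(probes)), index=[p.probe_id for p in probes])
tile_ids = [p.probe_id for p in probes if p.position in set(tile)]
values.loc[tile_ids] += 2.0  # planted promoter hypermethylation

scores = score_all_probes(probes, values, sample_id="T01")
peaks = find_peaks(scores, min_probes=2, score_threshold=2.0)
window = PromoterWindow("GENE1", "1", 1_196_500, 1_202_500, source_tss=1_201_500)
records = annotate_peaks(peaks, [window], probes)

hyper_tile = scores[(scores.direction == "hyper") & scores.probe_id.isin(tile_ids)]
print("tile hyper scores:", [round(s, 2) for s in hyper_tile.score])
for pk in peaks:
    print(f"peak: {pk.direction} chr{pk.chromosome}:{pk.start_bp}-{pk.end_bp} "
          f"({len(pk.probe_ids)} probes, mean score {pk.mean_score:.2f})")
print(records.to_string(index=False))
# aberrant_fraction = peak probes in the window / interrogated probes in it;
# 1.0 means the entire promoter tile sits inside the called peak
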