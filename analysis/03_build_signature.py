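#!/usr/bin/env python
"""Select hierarchical markers and assemble the deconvolution signature matrix.

Writes the signature under scratch/ (it is regenerated deterministically by
the pipeline) and a per-level marker summary under results/.
"""

from pathlib import Path

import pandas as pd

from nkdeconv import build_signature_matrix, gen_taxonomy, select_markers
from nkdeconv.nbmodel import PosteriorSet

ROOT = Path(__file__).resolve().parents[1]

taxonomy = gen_taxonomy()
posteriors = PosteriorSet.from_tsv(ROOT / "scratch" / "posteriors.tsv")
markers = select_markers(posteriors, taxonomy)
signature = build_signature_matrix(posteriors, markers, taxonomy)
signature.to_tsv(ROOT / "scratch" / "signature.tsv")

rows = []
for level in (1, 2, 3):
    pair_lists = markers.pairs_at_level(level)
    sizes = [len(g) for g in pair_lists.values()]
    rows.append(
        {
            "level": level,
            "ordered_pairs": len(pair_lists),
            "min_markers_per_pair": min(sizes),
            "max_markers_per_pair": max(sizes),
        }
    )
summary = pd.DataFrame(rows)
summary["marker_union"] = len(markers.union)
summary["signature_genes"] = len(signature.genes)
summary["signature_cell_types"] = len(signature.cell_types)
summary.to_csv(ROOT / "results" / "marker_summary.tsv", sep="\t", index=False)
print(summary.to_string(index=False))
print(
    f"\nSignature matrix: {len(signature.genes)} marker genes x "
    f"{len(signature.cell_types)} cell types."
)
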