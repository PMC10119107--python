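"""Gene-set Venn decomposition and cumulative-fraction (ECDF) comparison.

Integrates translation-level flags (differential pause positions, disome
peaks) with external per-gene protein fold changes: overlap counts between
2-4 gene sets, and a two-tailed Mann-Whitney comparison of a subset's
protein fold-change distribution against the full background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import mann_whitney


def venn_regions(sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Counts and memberships of all disjoint regions of 2-4 labelled sets.

    Each region is keyed by its membership pattern (one 0/1 flag per set
    label, at least one 1); counts sum to the size of the union.
    """
    labels = list(sets)
    if not 2 <= len(labels) <= 4:
        raise ValueError("venn_regions supports 2-4 sets")
    as_sets = {lab: set(sets[lab]) for lab in labels}
    universe = set().union(*as_sets.values())
    rows = []
    for pattern in product((1, 0), repeat=len(labels)):
        if not any(pattern):
            continue
        members = set(universe)
        for lab, bit in zip(labels, pattern):
            members &= as_sets[lab] if bit else universe - as_sets[lab]
        rows.append(
            {
                **{lab: bit for lab, bit in zip(labels, pattern)},
                "count": len(members),
                "members": ",".join(sorted(members)),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ECDFComparison:
    """Cumulative-fraction comparison of a gene subset against background."""

    background: np.ndarray  # sorted log2 fold changes
    subset: np.ndarray
    p: float  # two-tailed Mann-Whitney U
    median_difference: float  # subset median minus background median
    missing_ids: list[str] = field(default_factory=list)

    @staticmethod
    def _ecdf(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.sort(values)
        return x, np.arange(1, len(x) + 1) / len(x)

    def background_ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        return self._ecdf(self.background)

    def subset_ecdf(self) -> tuple[np.ndarray, np.ndarray]:
        return self._ecdf(self.subset)

    def table(self) -> pd.DataFrame:
        bx, by = self.background_ecdf()
        sx, sy = self.subset_ecdf()
        return pd.concat(
            [
                pd.DataFrame({"group": "background", "log2fc": bx, "cum_fraction": by}),
                pd.DataFrame({"group": "subset", "log2fc": sx, "cum_fraction": sy}),
            ],
            ignore_index=True,
        )


def cumulative_fraction_compare(
    fc: pd.Series,
    subset_ids: Sequence[str],
    inclusive_background: bool = True,
) -> ECDFComparison:
    """Compare protein fold changes of a gene subset with the background.

    ``fc`` maps gene id to log2 fold change; subset ids absent from the
    table are tallied in ``missing_ids`` (detection losses are expected with
    MS-based fold changes). The background includes subset members by
    default, matching cumulative-fraction figures that plot "all proteins"
    against the subset; ``inclusive_background=False`` uses the complement.
    """
    fc = fc.dropna()
    subset_ids = list(dict.fromkeys(subset_ids))
    present = [g for g in subset_ids if g in fc.index]
    missing = [g for g in subset_ids if g not in fc.index]
    if not present:
        raise ValueError("no subset id found in the fold-change table")
    subset = fc[present].to_numpy(float)
    if inclusive_background:
        background = fc.to_numpy(float)
    else:
        background = fc.drop(index=present).to_numpy(float)
    _, p = mann_whitney(subset, background)
    return ECDFComparison(
        background=np.sort(background),
        subset=np.sort(subset),
        p=p,
        median_difference=float(np.median(subset) - np.median(background)),
        missing_ids=missing,
    )


def read_protein_fold_changes(path) -> pd.Series:
    """Protein fold-change TSV: columns gene_id, log2fc."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "log2fc"} <= set(df.columns):
        raise ValueError(f"{path}: expected gene_id and log2fc columns")
    return df.set_index("gene_id")["log2fc"].astype(float)
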