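"""Hypergeometric over-representation analysis of a hit list.

For each gene set, the overlap k between the hit list (size n) and the
set restricted to the tested universe (size K, universe size N) is scored
with the upper-tail hypergeometric probability P(X >= k), and BH-adjusted
across all tested sets.  The universe is the population the hits were
drawn from — the genes passing the guide filter — not the whole genome.
"""

from __future__ import annotations

from typing import Collection

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .genescore import bh_adjust
from .io import GeneSetCollection, ScreenFormatError

__all__ = ["hypergeometric_enrichment"]

#: sets with fewer members inside the universe are uninformative and skipped
MIN_SET_SIZE = 3


def hypergeometric_enrichment(
    hits: Collection[str],
    collection: GeneSetCollection,
    universe: Collection[str],
) -> pd.DataFrame:
    """Test every gene set for over-representation among the hits.

    Returns a table (one row per tested set) with columns set, k, K, n, N,
    fold_enrichment, p_value, fdr, sorted by fdr then p then set name.

    Raises if any hit lies outside the universe (all offenders listed).
    """
    universe = set(universe)
    hits = set(hits)
    outside = sorted(hits - universe)
    if outside:
        raise ScreenFormatError(
            [f"hit {g!r} not in universe" for g in outside]
        )
    N = len(universe)
    n = len(hits)
    rows = []
    for name, members in collection:
        inset = members & universe
        K = len(inset)
        if K < MIN_SET_SIZE:
            continue
        k = len(inset & hits)
        p = float(np.clip(hypergeom.sf(k - 1, N, K, n), 0.0, 1.0)) if n else 1.0
        fold = (k / n) / (K / N) if n else 0.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N,
                     "fold_enrichment": fold, "p_value": max(p, 1e-300)})
    if not rows:
        return pd.DataFrame(
            columns=["set", "k", "K", "n", "N", "fold_enrichment", "p_value", "fdr"]
        )
    out = pd.DataFrame(rows)
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["fdr", "p_value", "set"]).reset_index(drop=True)
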