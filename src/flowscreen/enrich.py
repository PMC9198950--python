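"""Over-representation analysis of hit lists against the library background.

The statistic is the one-sided hypergeometric tail
P[X >= n_overlap] for X ~ Hypergeom(N = annotated background,
K = set size in background, n = annotated hits), optionally in the
conservative EASE variant (overlap decremented by one before taking the
tail), with Benjamini–Hochberg control across the tested sets.  The
background is the screened library, not the genome.  The descriptive
"percentage of category" statistic (100 * overlap / set size) is reported
alongside.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import GeneSetCollection


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(p, float), method="fdr_bh")[1]


def enrich(
    hits: Sequence[str],
    collection: GeneSetCollection,
    background: Sequence[str],
    min_set_size: int = 3,
    use_ease_for_q: bool = False,
) -> pd.DataFrame:
    """Test each gene set for over-representation of ``hits`` within the
    library ``background``.

    Sets are intersected with the background; sets smaller than
    ``min_set_size`` after intersection are skipped.  The hypergeometric
    universe N is the set of background genes annotated to at least one
    tested set (the DAVID convention), and hits are restricted to that
    universe.  An empty hit list is not an error: every overlap is 0 and
    every p-value 1.

    Returns a DataFrame sorted by p_hyper with columns set_name,
    n_background, n_set, n_hits, n_overlap, pct_of_category, p_hyper,
    p_ease, q_bh.
    """
    bg = set(background)
    stray = set(hits) - bg
    if stray:
        raise ValueError(
            f"hit gene(s) absent from background: {sorted(stray)[:5]}"
        )

    tested: dict[str, set[str]] = {}
    for name, members in collection.sets.items():
        inset = set(members) & bg
        if len(inset) >= min_set_size:
            tested[name] = inset
    if not tested:
        return pd.DataFrame(
            columns=[
                "set_name", "n_background", "n_set", "n_hits", "n_overlap",
                "pct_of_category", "p_hyper", "p_ease", "q_bh",
            ]
        )

    universe = set().union(*tested.values())
    N = len(universe)
    hit_set = set(hits) & universe
    n = len(hit_set)

    rows = []
    for name, inset in sorted(tested.items()):
        K = len(inset)
        k = len(inset & hit_set)
        # P[X >= k]; sf(k-1) is the survival function at k-1
        p_hyper = float(hypergeom.sf(k - 1, N, K, n))
        k_ease = max(k - 1, 0)
        p_ease = float(hypergeom.sf(k_ease - 1, N, K, n))
        rows.append(
            dict(
                set_name=name,
                n_background=N,
                n_set=K,
                n_hits=n,
                n_overlap=k,
                pct_of_category=100.0 * k / K,
                p_hyper=min(p_hyper, 1.0),
                p_ease=min(p_ease, 1.0),
            )
        )
    out = pd.DataFrame(rows)
    pcol = "p_ease" if use_ease_for_q else "p_hyper"
    out["q_bh"] = _bh_adjust(out[pcol].to_numpy())
    return out.sort_values(
        ["p_hyper", "set_name"], kind="mergesort"
    ).reset_index(drop=True)
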