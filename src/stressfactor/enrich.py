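"""Term-set over-representation testing with FDR control.

One-sided hypergeometric (Fisher) tests for enrichment of annotation terms
in a selected variable list against a universe, Benjamini-Hochberg adjusted
across terms.  Depletion (the lower tail) is available behind a flag.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io import AnnotationSets
from .stats import adjust_fdr


def fisher_enrichment(
    selection: set[str],
    universe: set[str],
    sets: AnnotationSets,
    alternative: str = "greater",
) -> pd.DataFrame:
    """Test each term for over-representation in ``selection``.

    Terms are intersected with the universe first.  For each term with
    ``n_term`` members, selection size ``n_sel`` and overlap ``a`` in a
    universe of ``N``, the one-sided p-value is the upper hypergeometric
    tail P(X >= a); the odds ratio is the sample odds ratio of the 2x2
    table (``inf`` when the off-diagonal empties).
    """
    if not universe:
        raise ValueError("empty universe")
    if not selection <= universe:
        extra = sorted(selection - universe)[:5]
        raise ValueError(f"selection not contained in universe: {extra}")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    sets = sets.restrict(universe)
    N = len(universe)
    n_sel = len(selection)
    rows = []
    for term in sets.term_ids:
        members = sets.members[term]
        n_term = len(members)
        a = len(selection & members)
        b = n_sel - a                      # selected, not in term
        c = n_term - a                     # in term, not selected
        d = N - n_sel - c                  # neither
        if alternative == "greater":
            p = float(hypergeom.sf(a - 1, N, n_term, n_sel))
        else:
            p = float(hypergeom.cdf(a, N, n_term, n_sel))
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append({
            "term_id": term,
            "term_name": sets.term_names[term],
            "overlap": a,
            "selection_size": n_sel,
            "term_size": n_term,
            "universe_size": N,
            "odds_ratio": odds,
            "p_value": min(p, 1.0),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = adjust_fdr(table["p_value"].to_numpy())
        table = table.sort_values("p_adjusted", kind="stable").reset_index(drop=True)
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
    return table
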