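"""Per-condition contrasts versus control and humidity Venn decomposition.

A one-way linear model on the six-level condition factor gives each stress
condition's log2 difference to control, with a pooled residual variance.
Comparing the regulated sets of a low- vs a high-humidity condition pair
(H_LrH vs H_HrH, or DH_LrH vs DH_HrH) splits the heat response into a
"dry air" component (low humidity only), a temperature component (both),
and a high-humidity-only component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import CONDITIONS, condition_series
from .matrix import OmicsMatrix, Thresholds
from .stats import adjust_fdr


def fit_condition_contrasts(m: OmicsMatrix, design: pd.DataFrame) -> pd.DataFrame:
    """Estimate each condition's contrast to control for every variable.

    One-way model on the condition factor; contrast estimate is the
    condition mean minus the control mean, standard errors use the pooled
    residual variance with n - n_conditions degrees of freedom.  BH
    adjustment is applied per contrast family (one condition across
    variables).
    """
    if m.scale != "log2":
        raise ValueError("condition contrasts expect log2-scale data")
    cond = condition_series(design, m.sample_ids).to_numpy()
    levels = [c for c in CONDITIONS if c in set(cond)]
    if "control" not in levels:
        raise ValueError("no control samples in design")
    n = m.n_samples
    df = float(n - len(levels))
    if df <= 0:
        raise ValueError("no residual degrees of freedom")

    means = {}
    counts = {}
    sse = np.zeros(m.n_variables)
    for c in levels:
        cols = cond == c
        counts[c] = int(cols.sum())
        means[c] = m.values[:, cols].mean(axis=1)
        sse += ((m.values[:, cols] - means[c][:, None]) ** 2).sum(axis=1)
    s2 = sse / df

    frames = []
    for c in levels:
        if c == "control":
            continue
        est = means[c] - means["control"]
        se = np.sqrt(s2 * (1.0 / counts[c] + 1.0 / counts["control"]))
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(se > 0, est / se, 0.0)
        p = 2.0 * sps.t.sf(np.abs(t), df=df)
        frames.append(pd.DataFrame({
            "variable_id": m.variable_ids,
            "condition": c,
            "estimate": est,
            "standard_error": se,
            "statistic": t,
            "df": df,
            "p_value": p,
            "p_adjusted": adjust_fdr(p),
        }))
    return pd.concat(frames, ignore_index=True)


def _regulated_sets(
    contrasts: pd.DataFrame, condition: str, th: Thresholds
) -> dict[str, set[str]]:
    sub = contrasts[contrasts["condition"] == condition]
    if sub.empty:
        raise ValueError(f"unknown condition label {condition!r}")
    sig = sub["p_adjusted"] < th.alpha
    return {
        "up": set(sub.loc[sig & (sub["estimate"] > th.lfc), "variable_id"]),
        "down": set(sub.loc[sig & (sub["estimate"] < -th.lfc), "variable_id"]),
    }


@dataclass(frozen=True)
class VennGroups:
    """Venn regions for one condition pair, split by direction."""

    condition_a: str
    condition_b: str
    a_only: dict[str, frozenset[str]]
    b_only: dict[str, frozenset[str]]
    overlap: dict[str, frozenset[str]]

    def region_counts(self) -> pd.DataFrame:
        rows = []
        for direction in ("up", "down"):
            rows.append({
                "direction": direction,
                "a_only": len(self.a_only[direction]),
                "overlap": len(self.overlap[direction]),
                "b_only": len(self.b_only[direction]),
            })
        return pd.DataFrame(rows)


def venn_decompose(
    contrasts: pd.DataFrame,
    condition_a: str,
    condition_b: str,
    th: Thresholds = Thresholds(),
) -> VennGroups:
    """Split regulated variables of two conditions into Venn regions.

    Membership is direction-specific: a variable up in A and down in B
    lands in A-only(up) and B-only(down).
    """
    a = _regulated_sets(contrasts, condition_a, th)
    b = _regulated_sets(contrasts, condition_b, th)
    a_only, b_only, overlap = {}, {}, {}
    for direction in ("up", "down"):
        a_only[direction] = frozenset(a[direction] - b[direction])
        b_only[direction] = frozenset(b[direction] - a[direction])
        overlap[direction] = frozenset(a[direction] & b[direction])
    return VennGroups(condition_a, condition_b, a_only, b_only, overlap)


def count_regulated(
    contrasts: pd.DataFrame, th: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Up/down counts per condition at the given thresholds."""
    rows = []
    for c in contrasts["condition"].unique():
        sets = _regulated_sets(contrasts, c, th)
        rows.append({
            "condition": c,
            "up": len(sets["up"]),
            "down": len(sets["down"]),
        })
    return pd.DataFrame(rows)
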