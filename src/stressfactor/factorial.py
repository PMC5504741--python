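"""Two-factor drought x heat interaction model and response-group calls.

Each variable (gene or metabolite mass) is fitted with the linear model

    y = b0 + bD * D + bH * H + bDH * D*H + error

over the four low-humidity design cells (control, D, H_LrH, DH_LrH); the
high-humidity cells are handled by the condition-contrast module.  The
interaction coefficient bDH measures how the combined-stress response
deviates from the sum of the single-stress responses.  Optionally, residual
variances are moderated by empirical-Bayes shrinkage toward a common prior
before t-statistics are formed.  Per-coefficient significance calls
(|log2FC| > lfc and FDR-adjusted p < alpha) then map each variable into one
of the response groups:

* rows: ``1.x`` reduced (interaction counteracts the single-stress
  regulation), ``2.x`` additive (no interaction), ``3.x`` enhanced
  (interaction reinforces), ``4`` specific (interaction only);
* columns: ``.1`` drought-only, ``.2`` shared same-sign, ``.3`` heat-only;
* rare opposite-sign single-stress patterns go to ``opp_additive`` /
  ``opp_interaction``; everything non-significant is ``null``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import FACTORIAL_CONDITIONS, condition_series
from .matrix import OmicsMatrix, Thresholds
from .stats import adjust_fdr, moderate_variances

COEF_NAMES = ("intercept", "D", "H", "D:H")
CALL_TERMS = ("D", "H", "D:H")

GROUP_LABELS = (
    "1.1", "1.2", "1.3",
    "2.1", "2.2", "2.3",
    "3.1", "3.2", "3.3",
    "4", "opp_additive", "opp_interaction", "null",
)


@dataclass
class FactorialFit:
    """Per-variable OLS results for the 2x2 factorial model."""

    variable_ids: list[str]
    coefficients: pd.DataFrame      # variables x (intercept, D, H, D:H)
    standard_errors: pd.DataFrame   # same shape, moderated if enabled
    residual_variance: np.ndarray   # raw s^2 per variable
    residual_df: float
    moderated: bool
    moderated_variance: np.ndarray | None = None
    prior_variance: float | None = None
    prior_df: float | None = None

    @property
    def total_df(self) -> float:
        if self.moderated:
            return self.residual_df + self.prior_df
        return self.residual_df

    def t_statistics(self) -> pd.DataFrame:
        return self.coefficients / self.standard_errors

    def p_values(self) -> pd.DataFrame:
        t = self.t_statistics().to_numpy()
        p = 2.0 * sps.t.sf(np.abs(t), df=self.total_df)
        return pd.DataFrame(p, index=self.variable_ids, columns=COEF_NAMES)


def fit_factorial_model(
    m: OmicsMatrix, design: pd.DataFrame, moderation: bool = True
) -> FactorialFit:
    """Fit the drought x heat model with interaction for every variable.

    Only samples from the four factorial conditions are used; genotypes are
    pooled.  With ``moderation`` the residual variances are shrunk toward a
    method-of-moments prior and the t degrees of freedom augmented by the
    prior degrees of freedom.
    """
    if m.scale != "log2":
        raise ValueError("factorial model expects log2-scale data")
    cond = condition_series(design, m.sample_ids)
    keep = cond.isin(FACTORIAL_CONDITIONS).to_numpy()
    sub = m.subset_samples([s for s, k in zip(m.sample_ids, keep) if k])
    cond = cond[keep]
    counts = cond.value_counts()
    missing = [c for c in FACTORIAL_CONDITIONS if counts.get(c, 0) < 2]
    if missing:
        raise ValueError(f"fewer than 2 replicates in design cell(s): {missing}")
    if not np.all(np.isfinite(sub.values)):
        raise ValueError("non-finite values in matrix")

    d = design.set_index("sample_id").loc[sub.sample_ids]
    D = d["drought"].to_numpy(float)
    H = d["heat"].to_numpy(float)
    X = np.column_stack([np.ones_like(D), D, H, D * H])
    n, k = X.shape
    df = float(n - k)

    Y = sub.values.T                       # samples x variables
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    s2 = (resid ** 2).sum(axis=0) / df
    xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))

    fit = FactorialFit(
        variable_ids=list(sub.variable_ids),
        coefficients=pd.DataFrame(
            beta.T, index=sub.variable_ids, columns=COEF_NAMES
        ),
        standard_errors=pd.DataFrame(
            np.sqrt(np.outer(s2, xtx_inv_diag)),
            index=sub.variable_ids, columns=COEF_NAMES,
        ),
        residual_variance=s2,
        residual_df=df,
        moderated=False,
    )
    if moderation:
        s2_tilde, s0_sq, d0 = moderate_variances(s2, df)
        fit.moderated = True
        fit.moderated_variance = s2_tilde
        fit.prior_variance = s0_sq
        fit.prior_df = d0
        fit.standard_errors = pd.DataFrame(
            np.sqrt(np.outer(s2_tilde, xtx_inv_diag)),
            index=sub.variable_ids, columns=COEF_NAMES,
        )
    return fit


def contrast_table(fit: FactorialFit) -> pd.DataFrame:
    """Long-format per-variable, per-term statistics with BH-adjusted p.

    The FDR family is one coefficient across all variables of the layer.
    """
    t = fit.t_statistics()
    p = fit.p_values()
    frames = []
    for term in CALL_TERMS:
        frames.append(pd.DataFrame({
            "variable_id": fit.variable_ids,
            "term": term,
            "estimate": fit.coefficients[term].to_numpy(),
            "standard_error": fit.standard_errors[term].to_numpy(),
            "statistic": t[term].to_numpy(),
            "df": fit.total_df,
            "p_value": p[term].to_numpy(),
            "p_adjusted": adjust_fdr(p[term].to_numpy()),
        }))
    return pd.concat(frames, ignore_index=True)


def call_significance(
    fit: FactorialFit, th: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Per-variable up/down/ns calls for the D, H and D:H coefficients."""
    table = contrast_table(fit)
    calls = pd.DataFrame("ns", index=fit.variable_ids, columns=list(CALL_TERMS))
    for term in CALL_TERMS:
        sub = table[table["term"] == term].set_index("variable_id")
        est = sub["estimate"]
        sig = sub["p_adjusted"] < th.alpha
        calls.loc[(est > th.lfc) & sig, term] = "up"
        calls.loc[(est < -th.lfc) & sig, term] = "down"
    return calls


_SIGN = {"up": 1, "down": -1, "ns": 0}


def classify_calls(call_d: str, call_h: str, call_i: str) -> tuple[str, str]:
    """Map one (D, H, D:H) call triple to (group label, direction).

    Total over the 27-point call space; every triple maps to exactly one of
    the thirteen labels.
    """
    sd, sh, si = _SIGN[call_d], _SIGN[call_h], _SIGN[call_i]
    if sd == 0 and sh == 0:
        if si == 0:
            return "null", "none"
        return "4", "up" if si > 0 else "down"
    if sd != 0 and sh != 0 and sd != sh:
        # opposite regulation between the single stresses (rare)
        if si == 0:
            return "opp_additive", "mixed"
        return "opp_interaction", "mixed"
    # remaining: a coherent single-stress direction exists
    direction = sd if sd != 0 else sh
    if sd != 0 and sh != 0:
        column = "2"                      # shared same-sign
    elif sd != 0:
        column = "1"                      # drought-only
    else:
        column = "3"                      # heat-only
    if si == 0:
        row = "2"                         # additive
    elif si == direction:
        row = "3"                         # enhanced
    else:
        row = "1"                         # reduced
    return f"{row}.{column}", "up" if direction > 0 else "down"


def classify_response_groups(calls: pd.DataFrame) -> pd.DataFrame:
    """Classify every variable from its three significance calls."""
    labels, directions = [], []
    for _, row in calls.iterrows():
        g, d = classify_calls(row["D"], row["H"], row["D:H"])
        labels.append(g)
        directions.append(d)
    return pd.DataFrame({
        "variable_id": calls.index,
        "D": calls["D"].to_numpy(),
        "H": calls["H"].to_numpy(),
        "D:H": calls["D:H"].to_numpy(),
        "group": labels,
        "direction": directions,
    }).set_index("variable_id")


def summarize_groups(groups: pd.DataFrame) -> pd.DataFrame:
    """Count variables per group x direction; counts partition the set."""
    counts = (
        groups.groupby(["group", "direction"], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    total = counts["count"].sum()
    assert total == len(groups)
    counts["fraction"] = counts["count"] / total
    return counts
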