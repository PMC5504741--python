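"""Matrix-level preprocessing for both omics layers.

Transcriptome: quantile normalization, log2, probe collapsing, batch
correction.  Metabolome: total-ion-current normalization, the 2/3 detection
filter, detection-floor imputation with log2, and batch / measurement-order
correction.  All operations return new matrices; none mutates its input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design import condition_series
from .matrix import OmicsMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BatchModelSpec:
    """Which factors to preserve vs remove during batch correction.

    ``preserve`` is the biological factor (condition); ``remove`` the
    nuisance factor (batch); ``order_column``, if given, names a numeric
    design column (e.g. replicate measurement order) removed as a linear
    covariate.
    """

    preserve: str = "condition"
    remove: str = "batch"
    order_column: str | None = None

    def __post_init__(self) -> None:
        removed = {self.remove}
        if self.order_column is not None:
            removed.add(self.order_column)
        if self.preserve in removed:
            raise ValueError("preserve and remove terms must be disjoint")


def quantile_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Force every sample's intensity distribution onto the common one.

    After normalization each column's sorted values equal the across-column
    mean of sorted values; ties within a column receive the mean of the
    reference values over their rank span.
    """
    if m.missing_mask.any():
        raise ValueError(
            "quantile normalization requires a complete matrix; "
            "normalize metabolome layers by TIC instead"
        )
    x = m.values
    reference = np.mean(np.sort(x, axis=0), axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty_like(col)
        i = 0
        while i < len(col):
            k = i
            while k + 1 < len(col) and col[order[k + 1]] == col[order[i]]:
                k += 1
            mapped[order[i : k + 1]] = reference[i : k + 1].mean()
            i = k + 1
        out[:, j] = mapped
    res = m.copy()
    res.values = out
    return res


def tic_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Scale each sample by its total ion current (sum of observed values).

    Columns are divided by their observed sum and rescaled by the mean
    column sum, so magnitudes stay comparable to the raw data.
    """
    if m.scale != "raw":
        raise ValueError("TIC normalization applies to raw-scale data")
    obs = ~m.missing_mask
    sums = np.where(obs, m.values, 0.0).sum(axis=0)
    if np.any(sums <= 0) or np.any((~obs).all(axis=0)):
        bad = [m.sample_ids[j] for j in np.where(sums <= 0)[0]]
        raise ValueError(f"column(s) with no observed values: {bad[:5]}")
    out = m.copy()
    out.values = m.values / sums * sums.mean()
    out.values[~obs] = np.nan
    return out


def filter_by_detection(
    m: OmicsMatrix, design: pd.DataFrame, detect_fraction: float = 2.0 / 3.0
) -> OmicsMatrix:
    """Keep variables detected in >= ``detect_fraction`` of the samples of
    at least one condition.

    Detection is read from the pre-imputation mask, so a floor-imputed
    value never counts as detected.
    """
    if not 0 < detect_fraction <= 1:
        raise ValueError("detect_fraction must lie in (0, 1]")
    cond = condition_series(design, m.sample_ids).to_numpy()
    obs = ~m.missing_mask
    keep = np.zeros(m.n_variables, dtype=bool)
    for c in pd.unique(cond):
        cols = cond == c
        n = int(cols.sum())
        if n == 0:
            raise ValueError(f"condition {c!r} has zero samples")
        frac = obs[:, cols].sum(axis=1) / n
        keep |= frac >= detect_fraction
    kept_ids = [v for v, k in zip(m.variable_ids, keep) if k]
    logger.info(
        "detection filter: kept %d of %d variables at fraction %.4f",
        len(kept_ids), m.n_variables, detect_fraction,
    )
    return m.subset_variables(kept_ids)


def impute_floor_and_log(m: OmicsMatrix, floor: float = 5.0e5) -> OmicsMatrix:
    """Set censored cells to the detection floor, then log2 everything.

    The mask is retained for provenance: downstream stages can still tell
    an imputed value from a measured one.
    """
    if m.scale != "raw":
        raise ValueError("floor imputation applies to raw-scale data")
    if floor <= 0:
        raise ValueError("detection floor must be positive")
    obs = ~m.missing_mask
    if np.any(m.values[obs] <= 0):
        raise ValueError("observed non-positive intensity; cannot log2")
    out = m.copy()
    out.values[~obs] = floor
    out.values = np.log2(out.values)
    out.scale = "log2"
    return out


def correct_batch(
    m: OmicsMatrix, design: pd.DataFrame, spec: BatchModelSpec = BatchModelSpec()
) -> OmicsMatrix:
    """Remove additive batch (and optional measurement-order) effects.

    Per variable, an additive linear model with the preserved condition
    factor plus sum-to-zero-coded batch (and a linear order covariate) is
    fitted by least squares; the fitted batch and order contributions are
    subtracted.  On balanced designs this removes batch means exactly while
    leaving condition-mean differences untouched.
    """
    if m.scale != "log2":
        raise ValueError("batch correction expects log2-scale data")
    d = design.set_index("sample_id").loc[m.sample_ids]
    cond = pd.get_dummies(d[spec.preserve], dtype=float).to_numpy()
    batches = pd.Categorical(d[spec.remove])
    n_batch = len(batches.categories)
    blocks: list[np.ndarray] = []
    if n_batch > 1:
        # sum-to-zero coding: last batch = -(sum of others)
        bz = np.zeros((len(d), n_batch - 1))
        codes = batches.codes
        for k in range(n_batch - 1):
            bz[codes == k, k] = 1.0
        bz[codes == n_batch - 1, :] = -1.0
        blocks.append(bz)
    if spec.order_column is not None:
        order = d[spec.order_column].astype(float).to_numpy()[:, None]
        blocks.append(order - order.mean())
    if not blocks:
        return m.copy()
    nuisance = np.hstack(blocks)
    X = np.hstack([cond, nuisance])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design: {spec.remove!r} (and/or "
            f"{spec.order_column!r}) confounded with {spec.preserve!r}"
        )
    beta, *_ = np.linalg.lstsq(X, m.values.T, rcond=None)
    fitted_nuisance = nuisance @ beta[cond.shape[1]:, :]
    out = m.copy()
    out.values = m.values - fitted_nuisance.T
    return out


def collapse_probes(
    m: OmicsMatrix, probe_to_gene: Mapping[str, str]
) -> OmicsMatrix:
    """Average probe rows mapping to the same gene; unmapped probes dropped."""
    groups: dict[str, list[int]] = {}
    dropped = 0
    for i, pid in enumerate(m.variable_ids):
        gene = probe_to_gene.get(pid)
        if gene is None:
            dropped += 1
            continue
        groups.setdefault(gene, []).append(i)
    if dropped:
        logger.info("collapse_probes: dropped %d unmapped probe(s)", dropped)
    if not groups:
        raise ValueError("no probe maps to any gene")
    genes = sorted(groups)
    values = np.vstack([m.values[groups[g]].mean(axis=0) for g in genes])
    return replace(
        m.copy(),
        values=values,
        variable_ids=genes,
        missing_mask=np.zeros_like(values, dtype=bool),
    )
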