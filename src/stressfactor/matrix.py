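"""Core in-memory containers for paired-omics matrices.

The central object is :class:`OmicsMatrix`, a variables-by-samples matrix of
intensities with an explicit missing-value mask.  Microarray-style
transcriptome matrices are complete by construction; mass-spectrometry peak
tables carry censored (below detection limit) entries, which are recorded in
the mask rather than imputed silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

LAYERS = ("transcriptome", "metabolome", "targeted_metabolome")
SCALES = ("raw", "log2")


@dataclass
class OmicsMatrix:
    """A variables x samples intensity matrix with a missingness mask.

    Parameters
    ----------
    values
        Real matrix, rows are variables (genes or metabolite masses),
        columns are samples.  Masked entries may hold any placeholder
        (conventionally ``nan``).
    variable_ids, sample_ids
        Ordered, unique identifiers for rows and columns.
    missing_mask
        Boolean matrix of the same shape; ``True`` marks a value that was
        not detected.  Must be all-``False`` for the transcriptome layer.
    layer
        One of ``transcriptome``, ``metabolome``, ``targeted_metabolome``.
    scale
        ``raw`` (positive intensities) or ``log2``.
    """

    values: np.ndarray
    variable_ids: list[str]
    sample_ids: list[str]
    missing_mask: np.ndarray | None = None
    layer: str = "transcriptome"
    scale: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.variable_ids = [str(v) for v in self.variable_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n_var, n_samp = self.values.shape
        if len(self.variable_ids) != n_var:
            raise ValueError(
                f"{len(self.variable_ids)} variable ids for {n_var} rows"
            )
        if len(self.sample_ids) != n_samp:
            raise ValueError(
                f"{len(self.sample_ids)} sample ids for {n_samp} columns"
            )
        if len(set(self.variable_ids)) != n_var:
            raise ValueError("duplicate variable id")
        if len(set(self.sample_ids)) != n_samp:
            raise ValueError("duplicate sample id")
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask shape does not match values")
        if self.layer == "transcriptome" and self.missing_mask.any():
            raise ValueError("transcriptome layer must be complete (no mask)")

    # ------------------------------------------------------------------
    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "OmicsMatrix":
        return replace(
            self,
            values=self.values.copy(),
            variable_ids=list(self.variable_ids),
            sample_ids=list(self.sample_ids),
            missing_mask=self.missing_mask.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        """Return values as a DataFrame (variables x samples)."""
        return pd.DataFrame(
            self.values, index=self.variable_ids, columns=self.sample_ids
        )

    def variable_index(self, ids: Sequence[str]) -> np.ndarray:
        pos = {v: i for i, v in enumerate(self.variable_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"unknown variable id(s): {missing[:5]}")
        return np.array([pos[i] for i in ids], dtype=int)

    def subset_variables(self, ids: Sequence[str]) -> "OmicsMatrix":
        idx = self.variable_index(ids)
        return replace(
            self,
            values=self.values[idx],
            variable_ids=[self.variable_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            missing_mask=self.missing_mask[idx],
        )

    def subset_samples(self, ids: Sequence[str]) -> "OmicsMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [i for i in ids if i not in pos]
        if missing:
            raise KeyError(f"unknown sample id(s): {missing[:5]}")
        idx = np.array([pos[i] for i in ids], dtype=int)
        return replace(
            self,
            values=self.values[:, idx],
            variable_ids=list(self.variable_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            missing_mask=self.missing_mask[:, idx],
        )

    def to_log2(self) -> "OmicsMatrix":
        """Return a log2-scaled copy; raw scale required, observed values > 0."""
        if self.scale != "raw":
            raise ValueError("matrix is already on log2 scale")
        obs = ~self.missing_mask
        if np.any(self.values[obs] <= 0):
            raise ValueError("non-positive observed intensity; cannot log2")
        out = self.copy()
        out.values[obs] = np.log2(self.values[obs])
        out.scale = "log2"
        return out


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds used across the pipeline.

    ``lfc`` and ``alpha`` drive differential calls (|log2 fold change| > lfc
    and FDR-adjusted p < alpha); ``edge_r``/``edge_alpha`` gate correlation
    network edges; ``sub_r`` is the relaxed cutoff for submodule views;
    ``detect_fraction`` and ``detection_floor`` drive metabolome filtering
    and imputation; ``top_variance_k`` and ``top_genes_per_mass`` bound the
    CCA variable selection and the clique-network gene reduction.
    """

    lfc: float = 1.0
    alpha: float = 0.05
    edge_r: float = 0.85
    sub_r: float = 0.75
    edge_alpha: float = 1.0e-5
    detect_fraction: float = 2.0 / 3.0
    detection_floor: float = 5.0e5
    top_variance_k: int = 100
    top_genes_per_mass: int = 3

    def __post_init__(self) -> None:
        if not self.lfc > 0:
            raise ValueError("lfc must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if not 0 < self.edge_r <= 1:
            raise ValueError("edge_r must lie in (0,1]")
        if not 0 < self.edge_alpha <= 1:
            raise ValueError("edge_alpha must lie in (0,1]")
        if not 0 < self.detect_fraction <= 1:
            raise ValueError("detect_fraction must lie in (0,1]")
        if not self.detection_floor > 0:
            raise ValueError("detection_floor must be positive")
        if self.top_variance_k <= 0 or self.top_genes_per_mass <= 0:
            raise ValueError("top-k parameters must be positive integers")
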