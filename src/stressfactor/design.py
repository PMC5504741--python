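"""Sample design handling: factors, condition labels, validation.

Samples are described by two binary stress factors (drought, heat), a
relative air humidity level that applies only under heat, a genotype and an
experimental batch.  The six experimental conditions are a pure function of
(drought, heat, humidity):

==========  =======  ====  ========
condition   drought  heat  humidity
==========  =======  ====  ========
control     0        0     ambient
D           1        0     ambient
H_LrH       0        1     low
H_HrH       0        1     high
DH_LrH      1        1     low
DH_HrH      1        1     high
==========  =======  ====  ========

LrH = heat applied at low relative air humidity (raised vapor pressure
deficit, the "dry air" component); HrH = heat with supplemented humidity.
"""

from __future__ import annotations

import pandas as pd

CONDITIONS = ("control", "D", "H_LrH", "H_HrH", "DH_LrH", "DH_HrH")
HUMIDITY_LEVELS = ("ambient", "low", "high")

#: conditions entering the two-factor drought x heat interaction model
FACTORIAL_CONDITIONS = ("control", "D", "H_LrH", "DH_LrH")

DESIGN_COLUMNS = ["sample_id", "drought", "heat", "humidity", "genotype", "batch"]


def derive_condition(drought: int, heat: int, humidity: str) -> str:
    """Map (drought, heat, humidity) to the condition label."""
    if humidity not in HUMIDITY_LEVELS:
        raise ValueError(f"unknown humidity level {humidity!r}")
    if heat == 0:
        if humidity != "ambient":
            raise ValueError(
                "humidity level only applies under heat; "
                f"got heat=0 with humidity={humidity!r}"
            )
        return "D" if drought else "control"
    if humidity == "ambient":
        raise ValueError("heat requires an explicit humidity level (low/high)")
    tag = "LrH" if humidity == "low" else "HrH"
    return f"DH_{tag}" if drought else f"H_{tag}"


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Validate a design table and attach the derived ``condition`` column.

    Returns a copy with columns ``sample_id, drought, heat, humidity,
    genotype, batch, condition`` (plus ``order`` if present).
    """
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing column(s): {missing}")
    out = design.copy()
    out["sample_id"] = out["sample_id"].astype(str)
    if out["sample_id"].duplicated().any():
        dup = out.loc[out["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    for col in ("drought", "heat"):
        vals = set(pd.unique(out[col].astype(int)))
        if not vals <= {0, 1}:
            raise ValueError(f"{col} must be binary 0/1, got {sorted(vals)}")
        out[col] = out[col].astype(int)
    out["humidity"] = out["humidity"].astype(str)
    out["condition"] = [
        derive_condition(d, h, hum)
        for d, h, hum in zip(out["drought"], out["heat"], out["humidity"])
    ]
    out["genotype"] = out["genotype"].astype(str)
    out["batch"] = out["batch"].astype(str)
    return out


def condition_series(design: pd.DataFrame, sample_ids: list[str]) -> pd.Series:
    """Condition labels for ``sample_ids``, in that order."""
    d = design.set_index("sample_id")
    missing = [s for s in sample_ids if s not in d.index]
    if missing:
        raise KeyError(f"sample id(s) absent from design: {missing[:5]}")
    return d.loc[sample_ids, "condition"]
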