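"""Free-ammonia speciation and elemental-ratio chemistry.

Total ammonium nitrogen (TAN) in an anaerobic digester partitions between
ionised ammonium (NH4+) and the un-ionised, membrane-permeable free ammonia
(NH3) that inhibits methanogenesis.  The equilibrium fraction depends on pH
through the acid dissociation constant Ka:

    NH3 = TAN / (1 + 10^(-pH) / Ka)

All concentrations are stored as g N L^-1 (numerically identical to
mg N mL^-1).  The default Ka of 1.20e-9 is the mesophilic (37 degC) value;
no temperature model is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import InvalidInputError

#: Ammonium acid dissociation constant at 37 degC (dimensionless).
KA_37C = 1.20e-9


@dataclass(frozen=True)
class ChemSample:
    """Per-sample ammonia speciation record.

    Attributes
    ----------
    sample_id : str
        Sample identifier ("" for anonymous computations).
    tan : float
        Total ammonium nitrogen, g N L^-1.
    ph : float
        pH, 0 < pH < 14.
    ka : float
        Acid dissociation constant used for the split.
    nh3 : float
        Free ammonia, g N L^-1.
    nh4 : float
        Ionised ammonium, g N L^-1 (``tan - nh3``).
    """

    sample_id: str
    tan: float
    ph: float
    ka: float
    nh3: float
    nh4: float

    def __post_init__(self) -> None:
        if abs((self.nh3 + self.nh4) - self.tan) > 1e-9:
            raise InvalidInputError("nh3 + nh4 must equal tan")
        if not (-1e-12 <= self.nh3 <= self.tan + 1e-12):
            raise InvalidInputError("nh3 must lie in [0, tan]")


def free_ammonia_speciation(
    tan: float, ph: float, ka: float = KA_37C, sample_id: str = ""
) -> ChemSample:
    """Split TAN into free ammonia and ionised ammonium at a given pH.

    Parameters
    ----------
    tan : float
        Total ammonium nitrogen, g N L^-1 (>= 0).
    ph : float
        pH in (0, 14).
    ka : float
        Dissociation constant (> 0); default mesophilic 1.20e-9.

    Returns
    -------
    ChemSample
        With ``nh3 = tan / (1 + 10**(-ph) / ka)`` and ``nh4 = tan - nh3``.
    """
    if tan < 0:
        raise InvalidInputError(f"tan must be >= 0, got {tan}")
    if not 0 < ph < 14:
        raise InvalidInputError(f"ph must be in (0, 14), got {ph}")
    if ka <= 0:
        raise InvalidInputError(f"ka must be > 0, got {ka}")
    nh3 = tan / (1.0 + 10.0 ** (-ph) / ka)
    return ChemSample(sample_id=sample_id, tan=tan, ph=ph, ka=ka, nh3=nh3, nh4=tan - nh3)


def cn_ratio(carbon: float, nitrogen: float) -> float:
    """Carbon-to-nitrogen mass ratio from % dry-mass measurements."""
    if nitrogen <= 0:
        raise InvalidInputError(f"nitrogen must be > 0, got {nitrogen}")
    return carbon / nitrogen


def speciate_metadata(metadata: pd.DataFrame, ka: float = KA_37C) -> pd.DataFrame:
    """Append ``nh3`` and ``nh4`` columns to a sample-metadata table.

    The table must carry ``tan`` and ``ph`` columns; a ``sample_id`` column
    is used for identifiers when present, otherwise the index.
    """
    for col in ("tan", "ph"):
        if col not in metadata.columns:
            raise InvalidInputError(f"metadata is missing required column {col!r}")
    out = metadata.copy()
    ids = out["sample_id"] if "sample_id" in out.columns else out.index
    records = [
        free_ammonia_speciation(float(t), float(p), ka, sample_id=str(s))
        for s, t, p in zip(ids, out["tan"], out["ph"])
    ]
    out["nh3"] = [r.nh3 for r in records]
    out["nh4"] = [r.nh4 for r in records]
    return out


def round_report(value: float, kind: str = "concentration") -> float:
    """Round for report output: 2 d.p. concentrations, 1 d.p. ratios."""
    if kind == "concentration":
        return round(value, 2)
    if kind == "ratio":
        return round(value, 1)
    raise InvalidInputError(f"unknown report kind {kind!r}")


def _nh3_limit_check(tan: float, ph: float, ka: float = KA_37C) -> float:
    # analytic convenience used in docs/tests: fraction of TAN that is NH3
    return 1.0 / (1.0 + math.pow(10.0, -ph) / ka)
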