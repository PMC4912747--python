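"""Free-ammonia speciation in anaerobic digesters.

Total ammonium nitrogen (TAN) in a digester is partitioned between the
ammonium ion (NH4+) and free, un-ionised ammonia (NH3).  Only the free
fraction crosses cell membranes freely and inhibits methanogens, so process
chemistry is characterised by the free-ammonia concentration rather than by
TAN itself.  The fraction is set by the NH4+/NH3 acid-base equilibrium:

    NH3 = TAN / (1 + 10^(-pH) / Ka(T)),   Ka(T) = 10^(-pKa(T))

with the temperature dependence of the dissociation constant taken from
Hansen, Angelidaki & Ahring (1998, Water Res. 32):

    pKa(T) = 0.09018 + 2729.92 / T_K

Concentrations are on a nitrogen basis (g N L^-1), the convention used in
digester monitoring tables; no N -> NH3 mass conversion is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["ammonia_pka", "free_ammonia", "annotate_records", "REQUIRED_COLUMNS"]

#: Hansen et al. (1998) coefficients for pKa(T), T in Kelvin.
PKA_INTERCEPT = 0.09018
PKA_SLOPE_K = 2729.92

#: Columns annotate_records needs to compute free ammonia.
REQUIRED_COLUMNS = ("tan_g_per_l", "ph", "temperature_c")


def ammonia_pka(temp_c: float) -> float:
    """pKa of the NH4+/NH3 couple at ``temp_c`` degrees Celsius."""
    temp_c = float(temp_c)
    if temp_c <= -273.15:
        raise ValueError(f"temperature below absolute zero: {temp_c} degC")
    return PKA_INTERCEPT + PKA_SLOPE_K / (temp_c + 273.15)


def free_ammonia(tan_g_per_l: float, ph: float, temp_c: float) -> float:
    """Free (un-ionised) ammonia from TAN, pH and temperature.

    Parameters
    ----------
    tan_g_per_l :
        Total ammonium nitrogen, g N L^-1 (NH4+-N plus NH3-N).
    ph :
        Digester pH, in (0, 14).
    temp_c :
        Process temperature, degrees Celsius, in (0, 80) for a digester.

    Returns
    -------
    float
        Free ammonia, g N L^-1, always within [0, tan].  Strictly
        increasing in both pH and temperature for tan > 0.
    """
    tan = float(tan_g_per_l)
    ph = float(ph)
    if tan < 0:
        raise ValueError(f"TAN must be non-negative, got {tan}")
    if not 0 < ph < 14:
        raise ValueError(f"pH out of range (0, 14): {ph}")
    if not 0 < float(temp_c) < 80:
        raise ValueError(f"temperature out of digester range (0, 80) degC: {temp_c}")
    pka = ammonia_pka(temp_c)
    # fraction un-ionised = 1 / (1 + [H+]/Ka) = 1 / (1 + 10^(pKa - pH))
    return tan / (1.0 + 10.0 ** (-ph) / 10.0 ** (-pka))


def annotate_records(
    records: pd.DataFrame,
    *,
    tan_col: str = "tan_g_per_l",
    ph_col: str = "ph",
    temp_col: str = "temperature_c",
    out_col: str = "ammonia_g_per_l",
    flag_col: str = "flag",
) -> pd.DataFrame:
    """Fill the free-ammonia column of a digester operating table row-wise.

    Rows with a missing pH, temperature or TAN are kept and flagged in
    ``flag_col`` (never silently dropped); their ammonia stays NaN.
    Non-numeric sentinel values elsewhere in the table (e.g. a VFA entry
    ``"<0.1"`` marking a below-detection measurement) are preserved verbatim.
    """
    out = records.copy()
    for col in (tan_col, ph_col, temp_col):
        if col not in out.columns and len(out) > 0:
            raise KeyError(f"required column missing: {col!r}")
    ammonia = np.full(len(out), np.nan)
    flags = [""] * len(out)
    for i, (_, row) in enumerate(out.iterrows()):
        vals = [pd.to_numeric(row[c], errors="coerce") for c in (tan_col, ph_col, temp_col)]
        if any(pd.isna(v) for v in vals):
            flags[i] = "missing_inputs"
            continue
        ammonia[i] = free_ammonia(*vals)
    out[out_col] = ammonia
    out[flag_col] = flags
    return out
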