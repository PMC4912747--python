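"""Bundled reference tables from a 10-plant survey of Swedish full-scale
anaerobic digesters (four co-digestion plants CD01-04, six wastewater
treatment plants WWTP01-06).

These small tables serve as worked inputs for the analysis modules:

* :func:`digester_operating_data` -- operating chemistry per plant (TS, VS,
  HRT, temperature, total N, pH, VFA, OLR, TAN, free ammonia, substrate).
* :func:`bmp_summary` -- batch degradation statistics per inoculum and
  substrate (days to 100/80/50 % of the final methane potential, final
  potential with replicate SD).
* :func:`diversity_summary` -- 16S rRNA gene alpha-diversity panel per
  plant at a rarefaction depth of 2500 reads (Chao1, observed OTUs,
  Shannon in bits, Simpson).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "digester_operating_data",
    "bmp_summary",
    "diversity_summary",
    "performance_table",
]


def _load(name: str) -> pd.DataFrame:
    with resources.files("digesta.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def digester_operating_data() -> pd.DataFrame:
    """Operating data for the ten full-scale plants, one row per digester.

    VFA values below the detection limit are kept as their sentinel string
    (e.g. ``"<0.1"``), so the column has object dtype.
    """
    return _load("digester_operating_data.tsv")


def bmp_summary() -> pd.DataFrame:
    """Batch methane-potential statistics per inoculum x substrate."""
    return _load("bmp_summary.tsv")


def diversity_summary() -> pd.DataFrame:
    """Alpha-diversity panel per plant (2500-read subsample)."""
    return _load("diversity_summary.tsv")


def performance_table() -> pd.DataFrame:
    """Constraint table for ordination: chemistry plus degradation rates.

    Joins the operating table with inverse days-to-50/80 % statistics from
    the batch tests: C50/C80 for cellulose, S50/S80 for straw (day^-1).
    Larger values mean faster degradation with that plant's inoculum.
    """
    ops = digester_operating_data().set_index("digester")
    bmp = bmp_summary()
    out = ops[["ammonia_g_per_l", "olr_gvs_per_l_day", "hrt_days"]].copy()
    out.columns = ["ammonia", "olr", "hrt"]
    out["vfa"] = pd.to_numeric(
        ops["vfa_g_per_l"].astype(str).str.lstrip("<"), errors="coerce"
    )
    for substrate, prefix in (("cellulose", "c"), ("straw", "s")):
        sub = bmp[bmp["substrate"] == substrate].set_index("inoculum")
        out[f"{prefix}_perf50"] = 1.0 / sub["days_to_50pct"]
        out[f"{prefix}_perf80"] = 1.0 / sub["days_to_80pct"]
    return out
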