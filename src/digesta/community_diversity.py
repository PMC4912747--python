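"""Alpha diversity of OTU count tables: rarefying, richness and evenness.

The survey convention implemented here: replicate libraries of one sample
are pooled in silico (element-wise count sums), every sample is randomly
subsampled without replacement to the depth of the shallowest sample
(2500 reads in the reference survey), and the index panel is computed on
the rarefied counts:

* observed OTUs (S_obs),
* Chao1 richness, bias-corrected form S_obs + F1(F1-1) / (2(F2+1)) with
  F1/F2 the singleton/doubleton counts (the classic F1^2/(2 F2) form is
  available via a flag),
* Shannon index in bits (base-2 logarithm; natural log via ``base``),
* Simpson index 1 - sum(p_i^2), the probability that two random reads
  come from different OTUs, and
* sequencing coverage, 100 * S_obs / Chao1 (percent of the estimated
  richness actually observed).

Rarefaction curves (mean richness across repeated subsamples over a depth
gradient) use the same without-replacement sampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiversityIndices",
    "pool_replicates",
    "subsample",
    "subsample_table",
    "chao1",
    "shannon",
    "simpson",
    "coverage_percent",
    "diversity_indices",
    "summarize_table",
    "rarefaction_curve",
]

DEFAULT_DEPTH = 2500


def _as_counts(counts: Sequence[int], allow_zero: bool = False) -> np.ndarray:
    arr = np.asarray(counts)
    if arr.size == 0:
        raise ValueError("empty count vector")
    if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
        raise ValueError("counts must be non-negative integers")
    arr = np.round(arr).astype(np.int64)
    if not allow_zero and arr.sum() == 0:
        raise ValueError("all-zero count vector")
    return arr


def pool_replicates(replicates: Sequence[Sequence[int]]) -> np.ndarray:
    """Pool replicate libraries in silico: element-wise count sum."""
    arrs = [_as_counts(r, allow_zero=True) for r in replicates]
    if len({a.size for a in arrs}) != 1:
        raise ValueError("replicates must share the OTU axis")
    return np.sum(arrs, axis=0)


def subsample(counts: Sequence[int], depth: int, seed=None, *, label: str = "") -> np.ndarray:
    """Rarefy one sample: draw ``depth`` reads without replacement.

    The output sums exactly to ``depth``.  ``seed`` may be an int or a
    ``numpy.random.Generator``.  A sample with fewer reads than ``depth``
    is rejected (rarefying cannot invent reads).
    """
    arr = _as_counts(counts)
    total = int(arr.sum())
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if total < depth:
        raise ValueError(f"sample {label or '<unnamed>'} has {total} reads < depth {depth}")
    if total == depth:
        return arr.copy()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.multivariate_hypergeometric(arr, depth).astype(np.int64)


def subsample_table(table: pd.DataFrame, depth: int, seed=None) -> pd.DataFrame:
    """Rarefy every column (sample) of an OTUs x samples count table."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = table.copy()
    for col in table.columns:
        out[col] = subsample(table[col].to_numpy(), depth, rng, label=str(col))
    return out


def chao1(counts: Sequence[int], *, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from singleton/doubleton counts.

    Always >= S_obs, with equality exactly when there are no singletons.
    """
    arr = _as_counts(counts)
    s_obs = int(np.count_nonzero(arr))
    f1 = int(np.sum(arr == 1))
    f2 = int(np.sum(arr == 2))
    if bias_corrected:
        return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon(counts: Sequence[int], *, base: float = 2.0) -> float:
    """Shannon diversity, base-2 by default (bits)."""
    arr = _as_counts(counts)
    p = arr[arr > 0] / arr.sum()
    return float(-(p * np.log(p)).sum() / np.log(base))


def simpson(counts: Sequence[int]) -> float:
    """Simpson diversity 1 - sum(p^2); 0 for a single OTU."""
    arr = _as_counts(counts)
    p = arr / arr.sum()
    return float(1.0 - (p**2).sum())


def coverage_percent(s_obs: float, chao1_estimate: float) -> float:
    """Sequencing coverage 100 * S_obs / Chao1, to one decimal place."""
    if not 0 < s_obs <= chao1_estimate:
        raise ValueError("need 0 < S_obs <= Chao1")
    return round(100.0 * s_obs / chao1_estimate, 1)


@dataclass(frozen=True)
class DiversityIndices:
    """Per-sample alpha-diversity panel."""

    s_obs: int
    chao1: float
    shannon: float
    simpson: float
    coverage_percent: float


def diversity_indices(counts: Sequence[int], *, shannon_base: float = 2.0) -> DiversityIndices:
    arr = _as_counts(counts)
    s = int(np.count_nonzero(arr))
    c = chao1(arr)
    return DiversityIndices(
        s_obs=s,
        chao1=c,
        shannon=shannon(arr, base=shannon_base),
        simpson=simpson(arr),
        coverage_percent=coverage_percent(s, c),
    )


def summarize_table(
    table: pd.DataFrame, *, depth: int | None = None, seed=None, shannon_base: float = 2.0
) -> pd.DataFrame:
    """Index panel for every sample of an OTUs x samples table.

    With ``depth`` given, each sample is first rarefied (one seeded stream
    for the whole run, recorded in ``DataFrame.attrs['subsample']``).
    """
    if depth is not None:
        table = subsample_table(table, depth, seed)
    rows = {}
    for col in table.columns:
        d = diversity_indices(table[col].to_numpy(), shannon_base=shannon_base)
        rows[col] = {
            "s_obs": d.s_obs,
            "chao1": d.chao1,
            "shannon": d.shannon,
            "simpson": d.simpson,
            "coverage_percent": d.coverage_percent,
        }
    out = pd.DataFrame(rows).T
    out.index.name = "sample"
    out["s_obs"] = out["s_obs"].astype(int)
    if depth is not None:
        out.attrs["subsample"] = {"depth": depth, "seed": seed}
    return out


def rarefaction_curve(
    counts: Sequence[int], depths: Sequence[int], *, reps: int = 10, seed=None
) -> pd.DataFrame:
    """Mean observed richness over ``reps`` seeded subsamples per depth."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    arr = _as_counts(counts)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for depth in depths:
        richness = [
            int(np.count_nonzero(subsample(arr, int(depth), rng))) for _ in range(reps)
        ]
        rows.append({"depth": int(depth), "mean_richness": float(np.mean(richness))})
    return pd.DataFrame(rows)
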