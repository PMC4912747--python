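"""Seeded generators for every input the analysis pipeline consumes.

Each generator is a pure function of its spec (which carries the seed):
the same spec always yields bit-identical output, and every generator
reports the ground truth it planted so downstream estimators can be tested
for recovery without any external data.

* :func:`simulate_bmp` -- cumulative specific methane curves for test and
  endogenous-control bottles.  The deterministic core is the modified
  Gompertz model M(t) = P exp(-exp((Rmax e / P)(lambda - t) + 1))
  (Zwietering et al. 1990), the standard saturating form for batch methane
  production, with i.i.d. additive Gaussian noise on the cumulative volume
  truncated at zero.  A first-order exponential core is available via the
  spec's ``model`` field.
* :func:`simulate_trflp` -- electropherogram peak tables: one peak per
  true ribotype with area proportional to its share, Gaussian size jitter,
  and sub-1 % baseline noise peaks placed away from true T-RFs so the
  background filter's behaviour is unambiguous.
* :func:`simulate_amplicons` -- random amplicons with restriction sites
  scrubbed and, optionally, one site planted at a known offset from the
  labelled end, so the predicted T-RF has a by-construction truth.
* :func:`simulate_otu_table` -- multinomial reads from lognormal
  relative abundances, with the true Shannon/Simpson of the underlying
  distribution reported per sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .insilico_digest import DEFAULT_ENZYMES, Enzyme

__all__ = [
    "BmpSimSpec",
    "TrflpSimSpec",
    "AmpliconSimSpec",
    "CommunitySimSpec",
    "BmpSimResult",
    "TrflpSimResult",
    "AmpliconSimResult",
    "OtuTableSimResult",
    "gompertz",
    "first_order",
    "time_to_fraction_true",
    "simulate_bmp",
    "simulate_trflp",
    "simulate_amplicons",
    "simulate_otu_table",
]


# ---------------------------------------------------------------------------
# BMP curves


def gompertz(t, final_potential: float, max_rate: float, lag: float):
    """Modified Gompertz cumulative methane curve.

    ``final_potential`` P (N mL g VS^-1), ``max_rate`` Rmax (N mL g VS^-1
    day^-1, the slope at the inflection), ``lag`` lambda (days).
    Non-decreasing in t and bounded by P.
    """
    t = np.asarray(t, dtype=float)
    inner = (max_rate * math.e / final_potential) * (lag - t) + 1.0
    return final_potential * np.exp(-np.exp(inner))


def first_order(t, final_potential: float, max_rate: float, lag: float):
    """First-order (exponential-rise) alternative: P(1 - exp(-k(t - lag))).

    The rate constant is k = max_rate / P so the initial slope after the
    lag equals ``max_rate``.
    """
    t = np.asarray(t, dtype=float)
    k = max_rate / final_potential
    return final_potential * (1.0 - np.exp(-k * np.clip(t - lag, 0.0, None)))


def time_to_fraction_true(spec: "BmpSimSpec", fraction: float) -> float:
    """Analytic time at which the noiseless model reaches fraction * P.

    For the Gompertz core: t = lambda + (1 - ln(-ln f)) * P / (Rmax e),
    which for f = 1/2 is lambda + (1 - ln ln 2) * P / (Rmax e).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1) for the analytic inverse")
    if spec.model == "gompertz":
        return spec.lag + (1.0 - math.log(-math.log(fraction))) * spec.final_potential / (
            spec.max_rate * math.e
        )
    k = spec.max_rate / spec.final_potential
    return spec.lag - math.log(1.0 - fraction) / k


@dataclass(frozen=True)
class BmpSimSpec:
    """Ground-truth kinetics and sampling design for one simulated condition."""

    final_potential: float = 350.0  # N mL CH4 g VS^-1, cellulose-like
    max_rate: float = 50.0  # N mL g VS^-1 day^-1
    lag: float = 2.0  # days
    sampling_days: tuple[float, ...] = tuple(range(1, 61))  # daily over a 60-day test
    noise_sd: float = 0.0  # N mL g VS^-1, additive on the cumulative value
    control_level: float = 0.1  # endogenous production as a fraction of P
    replicates: int = 3
    seed: int = 0
    model: str = "gompertz"  # or "first_order"

    def __post_init__(self) -> None:
        if self.final_potential <= 0 or self.max_rate <= 0:
            raise ValueError("final_potential and max_rate must be positive")
        if self.lag < 0 or self.noise_sd < 0 or not 0 <= self.control_level <= 1:
            raise ValueError("lag, noise_sd >= 0 and control_level in [0, 1] required")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        days = np.asarray(self.sampling_days, dtype=float)
        if days.size == 0 or np.any(np.diff(days) <= 0):
            raise ValueError("sampling_days must be non-empty and strictly increasing")
        if self.model not in ("gompertz", "first_order"):
            raise ValueError(f"unknown model {self.model!r}")


@dataclass
class BmpSimResult:
    days: np.ndarray
    test: np.ndarray  # replicates x days, cumulative N mL g VS^-1
    control: np.ndarray  # replicates x days
    t50_true: float  # analytic, continuous time
    spec: BmpSimSpec


def simulate_bmp(spec: BmpSimSpec) -> BmpSimResult:
    """Simulate test and endogenous-control cumulative curves.

    Controls follow the same kinetic model scaled to ``control_level * P``;
    test bottles produce the substrate-derived curve plus the same
    endogenous contribution (they contain inoculum too), so control
    subtraction recovers the substrate curve.  Noise is i.i.d. per sampling
    day, additive on the cumulative volume and truncated at zero (a
    cumulative volume cannot be negative).
    """
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.sampling_days, dtype=float)
    model = gompertz if spec.model == "gompertz" else first_order
    ctrl_p = spec.control_level * spec.final_potential
    if ctrl_p > 0:
        clean_ctrl = model(days, ctrl_p, spec.control_level * spec.max_rate, spec.lag)
    else:
        clean_ctrl = np.zeros_like(days)
    clean_test = model(days, spec.final_potential, spec.max_rate, spec.lag) + clean_ctrl

    def noisy(clean: np.ndarray) -> np.ndarray:
        out = np.tile(clean, (spec.replicates, 1))
        if spec.noise_sd > 0:
            out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
        return np.clip(out, 0.0, None)

    return BmpSimResult(
        days=days,
        test=noisy(clean_test),
        control=noisy(clean_ctrl),
        t50_true=time_to_fraction_true(spec, 0.5),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# T-RFLP electropherograms

#: Baseline noise peaks keep at least this distance (bp) from true T-RFs so
#: that filter tests are unambiguous.
BASELINE_EXCLUSION_BP = 3.0


@dataclass(frozen=True)
class TrflpSimSpec:
    """True ribotype T-RFs and noise model for one simulated lane."""

    true_trfs: tuple[tuple[float, float], ...]  # (size bp, relative share)
    size_jitter_sd: float = 0.0  # bp
    baseline_peaks: int = 0
    baseline_share: float = 0.005  # each noise peak's share of the true total area
    total_area: float = 100_000.0  # arbitrary fluorescence units
    seed: int = 0

    def __post_init__(self) -> None:
        shares = [s for _, s in self.true_trfs]
        if not self.true_trfs or abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError("true T-RF shares must sum to 1")
        if any(not 50.0 <= size <= 500.0 for size, _ in self.true_trfs):
            raise ValueError("true T-RF sizes must lie within the size-standard range [50, 500]")
        if self.size_jitter_sd < 0 or self.baseline_peaks < 0 or self.total_area <= 0:
            raise ValueError("invalid noise/area parameters")
        if not 0 < self.baseline_share < 0.01:
            raise ValueError("baseline peaks must each stay below 1 % of the total area")


@dataclass
class TrflpSimResult:
    peaks: pd.DataFrame  # sample, size_bp, height, area
    true_shares: dict[float, float]
    spec: TrflpSimSpec


def simulate_trflp(spec: TrflpSimSpec, sample_id: str = "S1") -> TrflpSimResult:
    """One lane's sized peak table with known true shares.

    True peaks carry area share * total_area and Gaussian size jitter;
    baseline peaks are placed uniformly on the calibration range but no
    closer than 3 bp to any true T-RF, each with an area strictly below
    1 % of the grand total so the background filter removes all of them.
    """
    rng = np.random.default_rng(spec.seed)
    sizes, areas = [], []
    for size, share in spec.true_trfs:
        jitter = rng.normal(0.0, spec.size_jitter_sd) if spec.size_jitter_sd > 0 else 0.0
        sizes.append(size + jitter)
        areas.append(share * spec.total_area)
    true_sizes = np.array([s for s, _ in spec.true_trfs])
    n_placed = 0
    while n_placed < spec.baseline_peaks:
        pos = rng.uniform(50.0, 500.0)
        if np.min(np.abs(true_sizes - pos)) <= BASELINE_EXCLUSION_BP:
            continue
        sizes.append(pos)
        # strictly below baseline_share of the raw total, hence below 1 %
        areas.append(spec.baseline_share * spec.total_area * rng.uniform(0.2, 1.0))
        n_placed += 1
    peaks = pd.DataFrame(
        {
            "sample": sample_id,
            "size_bp": sizes,
            "height": np.asarray(areas) / 10.0,  # nominal width
            "area": areas,
        }
    )
    return TrflpSimResult(peaks=peaks, true_shares=dict(spec.true_trfs), spec=spec)


# ---------------------------------------------------------------------------
# Amplicons with planted restriction sites


@dataclass(frozen=True)
class AmpliconSimSpec:
    """Random amplicons with scrubbed and optionally planted enzyme sites.

    ``planted_cut_positions`` gives, per sequence, the intended T-RF length
    (the cut's offset from the labelled 5' end) or None for an uncut
    amplicon whose truth is the full length.  A single value is broadcast.
    """

    n_sequences: int = 100
    length: int = 363  # cel5-amplicon-like
    planted_cut_positions: tuple[int | None, ...] | int | None = None
    enzyme_set: tuple[Enzyme, ...] = DEFAULT_ENZYMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 1 or self.length < 1:
            raise ValueError("n_sequences and length must be positive")
        if not self.enzyme_set:
            raise ValueError("enzyme_set must be non-empty")
        plant = self.enzyme_set[0]
        for pos in self.cut_positions():
            if pos is None:
                continue
            start = pos - plant.cut_offset
            if start < 0 or start + len(plant.recognition) > self.length:
                raise ValueError(
                    f"planted offset {pos} incompatible with {plant.name} site in a "
                    f"{self.length} bp amplicon"
                )

    def cut_positions(self) -> tuple[int | None, ...]:
        if self.planted_cut_positions is None or isinstance(self.planted_cut_positions, int):
            return (self.planted_cut_positions,) * self.n_sequences
        if len(self.planted_cut_positions) != self.n_sequences:
            raise ValueError("planted_cut_positions length must equal n_sequences")
        return tuple(self.planted_cut_positions)


@dataclass
class AmpliconSimResult:
    records: list[SeqRecord]
    truth: pd.DataFrame  # seq_id, true_trf, uncut
    spec: AmpliconSimSpec


def _scrub_sites(seq: list[str], enzymes: Sequence[Enzyme], rng: np.random.Generator) -> None:
    """Randomise bases until no enzyme recognition site remains (in place)."""
    bases = "ACGT"
    for _ in range(1000):
        s = "".join(seq)
        hit = min((s.find(e.recognition) for e in enzymes if e.recognition in s), default=-1)
        if hit < 0:
            return
        width = max(len(e.recognition) for e in enzymes)
        for i in range(hit, min(hit + width, len(seq))):
            seq[i] = bases[rng.integers(4)]
    raise RuntimeError("failed to scrub restriction sites")  # pragma: no cover


def simulate_amplicons(spec: AmpliconSimSpec) -> AmpliconSimResult:
    """Generate amplicons whose only labelled-end-proximal site is planted.

    Sequences are drawn uniformly over ACGT, every accidental recognition
    site of any enzyme in the set is scrubbed by local resampling, and the
    planted site (first enzyme of the set) is then written at the requested
    offset.  The reported truth is exactly the planted cut position, or the
    full length for site-free amplicons.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    plant = spec.enzyme_set[0]
    records, rows = [], []
    for i, pos in enumerate(spec.cut_positions()):
        for _attempt in range(100):
            seq = list(rng.choice(bases, size=spec.length))
            _scrub_sites(seq, spec.enzyme_set, rng)
            if pos is not None:
                start = pos - plant.cut_offset
                seq[start : start + len(plant.recognition)] = list(plant.recognition)
            s = "".join(seq)
            # verify the planting created no earlier accidental site
            cands = [
                s.find(e.recognition) + e.cut_offset
                for e in spec.enzyme_set
                if e.recognition in s
            ]
            expected = pos if pos is not None else None
            if (expected is None and not cands) or (cands and min(cands) == expected):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError(f"could not construct amplicon {i}")
        seq_id = f"amp{i:04d}"
        records.append(SeqRecord(Seq(s), id=seq_id, description=""))
        rows.append(
            {
                "seq_id": seq_id,
                "true_trf": pos if pos is not None else spec.length,
                "uncut": pos is None,
            }
        )
    return AmpliconSimResult(records=records, truth=pd.DataFrame(rows), spec=spec)


# ---------------------------------------------------------------------------
# OTU tables


@dataclass(frozen=True)
class CommunitySimSpec:
    """Lognormal-abundance community sampled multinomially to a fixed depth."""

    n_samples: int = 10
    richness: int = 100
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 1.0  # 0 gives a perfectly even community
    depth: int = 2500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.richness < 1 or self.depth < 1 or self.n_samples < 1:
            raise ValueError("richness, depth and n_samples must be >= 1")
        if self.lognormal_sigma < 0:
            raise ValueError("lognormal_sigma must be >= 0")


@dataclass
class OtuTableSimResult:
    counts: pd.DataFrame  # OTUs x samples, integer counts
    true_probs: np.ndarray  # samples x richness underlying relative abundances
    true_shannon_bits: np.ndarray  # per sample, of the underlying distribution
    true_simpson: np.ndarray
    spec: CommunitySimSpec


def simulate_otu_table(spec: CommunitySimSpec) -> OtuTableSimResult:
    """Independent lognormal abundance draws per sample, multinomial reads."""
    rng = np.random.default_rng(spec.seed)
    probs = np.empty((spec.n_samples, spec.richness))
    counts = np.empty((spec.richness, spec.n_samples), dtype=np.int64)
    for j in range(spec.n_samples):
        if spec.lognormal_sigma == 0:
            a = np.full(spec.richness, math.exp(spec.lognormal_mu))
        else:
            a = rng.lognormal(spec.lognormal_mu, spec.lognormal_sigma, spec.richness)
        p = a / a.sum()
        probs[j] = p
        counts[:, j] = rng.multinomial(spec.depth, p)
    shannon_true = -np.sum(np.where(probs > 0, probs * np.log2(probs), 0.0), axis=1)
    simpson_true = 1.0 - np.sum(probs**2, axis=1)
    table = pd.DataFrame(
        counts,
        index=[f"OTU{i:04d}" for i in range(spec.richness)],
        columns=[f"S{j + 1:02d}" for j in range(spec.n_samples)],
    )
    return OtuTableSimResult(
        counts=table,
        true_probs=probs,
        true_shannon_bits=shannon_true,
        true_simpson=simpson_true,
        spec=spec,
    )
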