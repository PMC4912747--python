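"""Terminal restriction fragment (T-RF) prediction from amplicon sequences.

In T-RFLP the amplicon pool carries a fluorescent label on the 5' end of
one primer (here the reverse primer, FAM-labelled); after restriction
digestion only the labelled terminal fragment is detected.  Given a clone
or amplicon sequence, the expected T-RF length is the number of labelled-
strand nucleotides 5' of the first cut - including the labelled primer
itself.  Comparing predicted lengths with observed electropherogram peaks
links fingerprint T-RFs back to sequenced ribotypes.

The built-in enzyme registry covers the two enzymes used for the cel5/cel48
glycoside-hydrolase markers: MboI (cuts ^GATC, i.e. before the site) and
AluI (AG^CT, blunt cut after the second base).  By default a double digest
is assumed (the earliest cut by any enzyme terminates the fragment);
passing a single enzyme gives single-digest semantics.

Sizes predicted in silico and sizes read off a capillary trace differ by
small electrophoretic-mobility offsets, so observed-to-predicted matching
is tolerance-based (default +/-2 bp) and deliberately one-to-many: distinct
sequences can share a T-RF size, and all candidates within tolerance are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "Enzyme",
    "PrimerPair",
    "AmpliconModel",
    "TrfPrediction",
    "UnorientableError",
    "ENZYMES",
    "MBOI",
    "ALUI",
    "CEL5_PRIMERS",
    "CEL48_PRIMERS",
    "iupac_match",
    "orient_to_labeled_strand",
    "predict_trf",
    "predict_trf_table",
    "match_trf_to_otus",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme: recognition sequence and cut offset.

    ``cut_offset`` is 0-based within the recognition site, counted on the
    labelled strand: MboI (^GATC) has offset 0, AluI (AG^CT) offset 2.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition or any(b not in "ACGT" for b in self.recognition):
            raise ValueError(f"recognition site must be plain ACGT: {self.recognition!r}")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError("cut offset must lie within the recognition site")


MBOI = Enzyme("MboI", "GATC", 0)
ALUI = Enzyme("AluI", "AGCT", 2)
ENZYMES: dict[str, Enzyme] = {"MboI": MBOI, "AluI": ALUI}

DEFAULT_ENZYMES: tuple[Enzyme, ...] = (MBOI, ALUI)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primer pair; one carries the fluorescent label."""

    forward: str
    reverse: str
    labeled: str = "reverse"

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not seq or any(b not in IUPAC for b in seq.upper()):
                raise ValueError(f"primer must be non-empty IUPAC: {seq!r}")
        if self.labeled not in ("forward", "reverse"):
            raise ValueError("labeled must be 'forward' or 'reverse'")

    @property
    def labeled_primer(self) -> str:
        return (self.reverse if self.labeled == "reverse" else self.forward).upper()


#: Glycoside hydrolase family 5 marker primers (cel5_392F / cel5_754R,
#: FAM label on the reverse primer).
CEL5_PRIMERS = PrimerPair(
    forward="GAGCATGGGCTGGAAYHTNGGNAA",
    reverse="CATCATAATCTTTGAAGTGGTTTGCAATYTGDKTCCA",
    labeled="reverse",
)
#: Family 48 marker primers (cel48_490F / cel48_920R, FAM on reverse).
CEL48_PRIMERS = PrimerPair(
    forward="TNATGGTTGAAGCTCCDGAYTAYGG",
    reverse="CCAAANCCRTACCAGTTRTCAACRTC",
    labeled="reverse",
)


@dataclass(frozen=True)
class AmpliconModel:
    """Amplicon oriented so position 0 is the labelled primer's 5' end."""

    seq_id: str
    sequence: str
    enzymes: tuple[Enzyme, ...] = DEFAULT_ENZYMES

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")


class UnorientableError(ValueError):
    """Neither strand of a sequence starts with the labelled primer."""


def iupac_match(pattern: str, text: str, max_mismatch: int = 0) -> bool:
    """Does ``text`` match the degenerate ``pattern`` with at most
    ``max_mismatch`` mismatches?  Lengths must be equal."""
    if len(pattern) != len(text):
        return False
    mismatches = 0
    for p, t in zip(pattern.upper(), text.upper()):
        if t not in IUPAC.get(p, ""):
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def _find_primer_start(seq: str, primer: str, max_mismatch: int, slack: int) -> int | None:
    """Leftmost start within ``slack`` bases of the 5' end, or None."""
    for start in range(0, slack + 1):
        if start + len(primer) <= len(seq) and iupac_match(primer, seq[start : start + len(primer)], max_mismatch):
            return start
    return None


def orient_to_labeled_strand(
    sequence: str,
    primers: PrimerPair,
    *,
    seq_id: str = "",
    enzymes: Sequence[Enzyme] = DEFAULT_ENZYMES,
    max_mismatch: int = 2,
    end_slack: int = 5,
) -> AmpliconModel:
    """Return the strand whose 5' terminus is the labelled primer's 5' end.

    Deposited clones may be stored in either orientation, so both the
    sequence and its reverse complement are checked for the labelled primer
    near the 5' end (IUPAC degeneracy honoured, a small mismatch budget and
    positional slack allowed).  Orientation is an involution: feeding in the
    reverse complement yields the identical model.
    """
    raw = sequence.upper().replace("U", "T")
    if any(b not in "ACGT" for b in raw):
        raise ValueError("sequence must contain only A/C/G/T")
    primer = primers.labeled_primer
    candidates = (raw, str(Seq(raw).reverse_complement()))
    for cand in candidates:
        start = _find_primer_start(cand, primer, max_mismatch, end_slack)
        if start is not None:
            return AmpliconModel(seq_id=seq_id, sequence=cand[start:], enzymes=tuple(enzymes))
    raise UnorientableError(
        f"{seq_id or 'sequence'}: labelled primer {primer!r} not found within "
        f"{max_mismatch} mismatches near the 5' end of either strand"
    )


@dataclass(frozen=True)
class TrfPrediction:
    """Predicted terminal fragment for one amplicon."""

    seq_id: str
    length: int
    enzyme: str | None  # None when uncut
    uncut: bool


def predict_trf(model: AmpliconModel, enzymes: Sequence[Enzyme] | None = None) -> TrfPrediction:
    """Predicted T-RF length (bp) for an oriented amplicon.

    For each enzyme the first occurrence of its recognition sequence on the
    labelled strand yields a candidate fragment of ``start + cut_offset``
    nucleotides; the shortest candidate over all enzymes wins (double-digest
    semantics).  If no enzyme site exists the full amplicon length is
    returned flagged ``uncut``.
    """
    seq = model.sequence.upper()
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"{model.seq_id or 'sequence'}: non-ACGT characters in digest target")
    enzymes = tuple(enzymes) if enzymes is not None else model.enzymes
    best: tuple[int, str] | None = None
    for enz in enzymes:
        idx = seq.find(enz.recognition)
        if idx >= 0:
            cand = idx + enz.cut_offset
            if best is None or cand < best[0]:
                best = (cand, enz.name)
    if best is None:
        return TrfPrediction(model.seq_id, len(seq), None, True)
    return TrfPrediction(model.seq_id, best[0], best[1], False)


def predict_trf_table(models: Iterable[AmpliconModel], enzymes: Sequence[Enzyme] | None = None) -> pd.DataFrame:
    """Tabulate predictions for many amplicons."""
    rows = [predict_trf(m, enzymes) for m in models]
    return pd.DataFrame(
        {
            "seq_id": [r.seq_id for r in rows],
            "predicted_trf": [r.length for r in rows],
            "enzyme": [r.enzyme for r in rows],
            "uncut": [r.uncut for r in rows],
        }
    )


def match_trf_to_otus(
    observed: Sequence[float],
    predicted: Sequence[tuple[str, float]],
    tolerance: float = 2.0,
) -> pd.DataFrame:
    """Assign observed T-RF sizes to all predicted OTU fragments within tolerance.

    One observed size may map to several OTUs (distinct sequences often
    share a T-RF length), and one OTU may absorb several observed sizes.
    Unmatched observations are reported with a null ``otu_id`` rather than
    dropped.  The assignment set grows monotonically with tolerance.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    rows = []
    for obs in observed:
        hits = [(otu, size) for otu, size in predicted if abs(size - obs) <= tolerance]
        if not hits:
            rows.append({"observed_trf": obs, "otu_id": None, "predicted_trf": None, "delta": None})
        for otu, size in hits:
            rows.append({"observed_trf": obs, "otu_id": otu, "predicted_trf": size, "delta": size - obs})
    return pd.DataFrame(rows, columns=["observed_trf", "otu_id", "predicted_trf", "delta"])
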