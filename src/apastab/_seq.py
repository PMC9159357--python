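"""Small sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C over A/C/G/T bases; NaN for empty input."""
    seq = seq.upper()
    n = sum(seq.count(b) for b in "ACGT")
    if n == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / n


def u_fraction(seq: str) -> float:
    """Fraction of U (T in DNA space) over A/C/G/T bases; NaN for empty."""
    seq = seq.upper()
    n = sum(seq.count(b) for b in "ACGT")
    if n == 0:
        return float("nan")
    return seq.count("T") / n


def base_fractions(seq: str) -> dict[str, float]:
    """Per-base fractions over {A, C, G, U}; sums to 1 for non-empty input."""
    seq = seq.upper()
    n = sum(seq.count(b) for b in "ACGT")
    if n == 0:
        return {b: float("nan") for b in "ACGU"}
    return {
        "A": seq.count("A") / n,
        "C": seq.count("C") / n,
        "G": seq.count("G") / n,
        "U": seq.count("T") / n,
    }
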