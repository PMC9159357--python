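"""3'UTR secondary-structure propensity scoring.

A 3'UTR is scanned in 100-nt windows with 50-nt overlap; each window's
minimum folding energy (MFE) is computed by a pluggable engine and the
median over windows represents the whole sequence.  Per-position
structure-probing signal (DMS-style reactivities) is summarized the same
way via windowed Gini indices; a high Gini index indicates uneven
reactivity, i.e. likely secondary structure.

Two engines are provided: a built-in Nussinov-style maximum-base-pairing
surrogate (minimum loop length 3; -1 per GC/AU/GU pair) whose score is a
pseudo-energy — NOT a thermodynamic kcal/mol value — and an adapter that
shells out to ViennaRNA's RNAfold when it is installed for true MFE in
kcal/mol.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from typing import Optional, Protocol, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100
DEFAULT_STEP = 50

_PAIRS = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}
_PAIR_LUT = np.zeros((256, 256), dtype=bool)
for _a, _b in _PAIRS:
    _PAIR_LUT[ord(_a), ord(_b)] = True


def _pair_matrix(code: np.ndarray) -> np.ndarray:
    return _PAIR_LUT[code[:, None], code[None, :]]


class FoldingEngine(Protocol):
    """Contract: ``fold(sequence) -> MFE`` with MFE <= 0 always (the
    empty structure has energy 0)."""

    name: str

    def fold(self, sequence: str) -> float: ...


def window_sequence(
    sequence: str, win: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP
) -> list[tuple[int, int]]:
    """Sub-sequence windows [start, start+win) at starts 0, step, 2*step...

    Only full windows are kept (start + win <= L); a sequence shorter
    than ``win`` yields a single full-length window.
    """
    L = len(sequence)
    if L < 1:
        raise ValueError("empty sequence")
    if L < win:
        return [(0, L)]
    return [(s, s + win) for s in range(0, L - win + 1, step)]


def n_windows(length: int, win: int = DEFAULT_WINDOW, step: int = DEFAULT_STEP) -> int:
    """Closed-form window count: 1 if L < win else floor((L-win)/step)+1."""
    if length < 1:
        raise ValueError("empty sequence")
    if length < win:
        return 1
    return (length - win) // step + 1


class NussinovEngine:
    """Maximum base-pairing surrogate folding engine.

    Dynamic-programming maximization of Watson-Crick + GU wobble pairs
    with a minimum hairpin loop of ``min_loop`` unpaired bases; the
    score is -1 per pair, a pseudo-energy on an arbitrary scale that
    ranks pairing potential but is not thermodynamic.
    """

    name = "nussinov"

    def __init__(self, min_loop: int = 3):
        self.min_loop = min_loop

    def fold(self, sequence: str) -> float:
        s = sequence.upper().replace("T", "U")
        n = len(s)
        if n == 0:
            return 0.0
        m = self.min_loop
        code = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        can_pair = _pair_matrix(code)
        dp = np.zeros((n, n), dtype=np.int32)
        # anti-diagonal sweep, vectorized over i for each span
        for span in range(m + 1, n):
            i = np.arange(0, n - span)
            j = i + span
            best = np.where(can_pair[i, j], dp[i + 1, j - 1] + 1, 0)
            np.maximum(best, dp[i + 1, j], out=best)
            np.maximum(best, dp[i, j - 1], out=best)
            for off in range(1, span):  # bifurcation at k = i + off
                np.maximum(best, dp[i, i + off] + dp[i + off + 1, j], out=best)
            dp[i, j] = best
        return -float(dp[0, n - 1])


class RNAfoldEngine:
    """Thermodynamic MFE via ViennaRNA's RNAfold executable (kcal/mol)."""

    name = "rnafold"

    def __init__(self, executable: str = "RNAfold"):
        self.executable = executable
        if shutil.which(executable) is None:
            raise RuntimeError(f"{executable} not found on PATH")

    def fold(self, sequence: str) -> float:
        out = subprocess.run(
            [self.executable, "--noPS"],
            input=sequence.upper().replace("T", "U") + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout
        # last line: "....structure.... ( -12.30 )"
        line = out.strip().splitlines()[-1]
        energy = line[line.rindex("(") + 1 : line.rindex(")")]
        return min(0.0, float(energy))


def get_engine(name: str = "builtin") -> FoldingEngine:
    if name in ("builtin", "nussinov"):
        return NussinovEngine()
    if name in ("external", "rnafold", "vienna"):
        return RNAfoldEngine()
    raise ValueError(f"unknown folding engine {name!r}")


def median_mfe(
    sequence: str,
    engine: Optional[FoldingEngine] = None,
    win: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> float:
    """Median windowed MFE of a sequence; NaN if every window fails."""
    engine = engine or NussinovEngine()
    vals = []
    for a, b in window_sequence(sequence, win, step):
        try:
            vals.append(engine.fold(sequence[a:b]))
        except Exception as exc:  # engine failure: skip window
            logger.warning("folding failed on window %d-%d: %s", a, b, exc)
    if not vals:
        return float("nan")
    return float(np.median(vals))


def gini(values: Sequence[float]) -> float:
    """Gini index G = sum_ij |x_i - x_j| / (2 n^2 mean(x)).

    Values must be non-negative; all-zero input has no defined index and
    returns NaN.  G lies in [0, 1 - 1/n] and is permutation-invariant.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if x.size == 0:
        raise ValueError("empty input")
    if np.any(x < 0):
        raise ValueError("values must be >= 0")
    total = x.sum()
    if total == 0:
        return float("nan")
    n = x.size
    i = np.arange(1, n + 1)
    return float(2.0 * (i * x).sum() / (n * total) - (n + 1) / n)


def median_gini(
    values: Sequence[float],
    win: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> float:
    """Median of per-window Gini indices over a per-position signal,
    using the same 100/50 windowing as the MFE scan."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty signal")
    ginis = []
    for a, b in window_sequence("N" * x.size, win, step):
        w = x[a:b]
        if w.sum() > 0:
            ginis.append(gini(w))
    if not ginis:
        return float("nan")
    return float(np.median(ginis))


def structure_profile(
    region_id: str,
    sequence: str,
    engine: Optional[FoldingEngine] = None,
    signal: Optional[Sequence[float]] = None,
    win: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> dict:
    """Windowed MFE (and optional probing-signal Gini) summary of one
    region; returns a flat record suitable for a TSV row."""
    rec = {
        "region_id": region_id,
        "length": len(sequence),
        "n_windows": n_windows(len(sequence), win, step),
        "median_MFE": median_mfe(sequence, engine, win, step),
    }
    if signal is not None:
        rec["median_gini"] = median_gini(signal, win, step)
    return rec
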