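"""Kappa Index of Coincidence and relative (C+G)% sliding-window numerics.

The Kappa Index of Coincidence (KIC) adapts the cryptographic index of
coincidence to a single DNA sequence: the window is compared against every
shifted copy of itself, and the percentage of positionwise matches is averaged
over all shifts.  A homopolymer scores exactly 100; an i.i.d. uniform random
window scores about 25 (match probability 1/4 per position).  Short tandem
repeats and homopolymer tracts push the value up, which is what makes KIC a
useful scalar for promoter architecture.

Relative (C+G)% re-expresses each window's C+G fraction on the scale of the
whole promoter: ``CG_sw = cg_total / (countable bases in window) * (C+G in
window)``, so an all-C/G window returns ``cg_total`` itself and the value
never exceeds it.

Two shift conventions are provided for the self-coincidence sum over a window
``A`` of length ``L`` with ``N = L - 1`` shifts:

``"full"`` (default)
    shift ``u`` compares ``A[0:L-u]`` with the full suffix ``A[u:L]``
    (``L - u`` comparisons).  This is the convention under which a
    homopolymer scores exactly 100.00.
``"literal"``
    shift ``u`` compares against the suffix truncated before the final
    character (``L - 1 - u`` comparisons); the empty final shift contributes
    nothing.  The divisor is ``N`` in both modes and the result is rounded to
    two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sequence_io import PromoterRecord

__all__ = [
    "WindowParams",
    "WindowProfile",
    "kappa_ic",
    "cg_percent_total",
    "cg_percent_window",
    "window_profile",
    "n_windows",
]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4
_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c
    _ENCODE_TABLE[ord(_b.lower())] = _c


def encode(sequence: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A,C,G,T,N -> 0..4)."""
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    codes = _ENCODE_TABLE[raw]
    bad = np.nonzero(codes == 255)[0]
    if bad.size:
        pos = int(bad[0])
        raise ValueError(
            f"illegal character {sequence[pos]!r} at position {pos + 1}"
        )
    return codes


@dataclass(frozen=True)
class WindowParams:
    """Sliding-window parameters: 30 nt windows advanced 1 nt at a time."""

    window_size: int = 30
    step: int = 1
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.mode not in ("full", "literal"):
            raise ValueError(f"unknown KIC mode {self.mode!r}")


@dataclass
class WindowProfile:
    """Per-window paired series (relative CG%, KIC%) for one promoter."""

    promoter_id: str
    params: WindowParams
    cg_values: np.ndarray
    kic_values: np.ndarray
    cg_total: float
    window_starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    n_skipped: int = 0

    @property
    def n_windows(self) -> int:
        return len(self.kic_values)

    def __post_init__(self) -> None:
        self.cg_values = np.asarray(self.cg_values, dtype=float)
        self.kic_values = np.asarray(self.kic_values, dtype=float)
        if self.cg_values.shape != self.kic_values.shape:
            raise ValueError("cg_values and kic_values must have equal length")


def n_windows(length: int, params: WindowParams) -> int:
    """Number of sliding windows for a sequence of the given length.

    The convention is ``floor((L - window_size) / step)`` windows starting at
    offsets 0, step, 2*step, ...: a 500 nt promoter profiled at window 30 and
    step 1 yields exactly 470 windows, i.e. 470 pattern lines.
    """
    if length <= params.window_size:
        return 0
    return (length - params.window_size) // params.step


def _kic_from_counts(match_counts: list[np.ndarray], window: int, mode: str) -> np.ndarray:
    """Combine per-shift match counts into the per-window KIC percentage."""
    n_shifts = window - 1
    total = np.zeros_like(match_counts[0], dtype=float)
    for u, counts in enumerate(match_counts, start=1):
        if mode == "full":
            total += counts / (window - u) * 100.0
        else:  # literal: suffix truncated before the last character
            denom = window - 1 - u
            if denom > 0:
                total += counts / denom * 100.0
    return np.round(total / n_shifts, 2)


def kappa_ic(window_seq: str, mode: str = "full") -> float:
    """Kappa Index of Coincidence of a single window, in percent.

    Averages, over all shifts ``u = 1 .. len-1``, the percentage of positions
    at which the window matches its own shifted copy, and rounds to two
    decimals.  Requires length >= 2 over ``{A,C,G,T}``.
    """
    if len(window_seq) < 2:
        raise ValueError("window too short: KIC requires length >= 2")
    codes = encode(window_seq)
    if np.any(codes == _N_CODE):
        raise ValueError("KIC is undefined for windows containing N")
    L = len(codes)
    if mode == "literal":
        counts = [
            np.array([int(np.count_nonzero(codes[: L - 1 - u] == codes[u : L - 1]))])
            for u in range(1, L)
        ]
    else:
        counts = [
            np.array([int(np.count_nonzero(codes[: L - u] == codes[u:]))])
            for u in range(1, L)
        ]
    return float(_kic_from_counts(counts, L, mode)[0])


def cg_percent_total(sequence: str) -> float:
    """Whole-promoter (C+G)%: ``100 / (#A+#T+#C+#G) * (#C+#G)``.

    ``N`` bases are not countable; a sequence with zero countable bases is an
    error.
    """
    if not sequence:
        raise ValueError("empty sequence")
    codes = encode(sequence)
    countable = int(np.count_nonzero(codes != _N_CODE))
    if countable == 0:
        raise ValueError("sequence has no countable A/C/G/T bases")
    cg = int(np.count_nonzero((codes == _CODE["C"]) | (codes == _CODE["G"])))
    return 100.0 / countable * cg


def cg_percent_window(window_cg: int, window_countable: int, cg_total: float) -> float:
    """Relative (C+G)% of one window: ``cg_total / countable * cg``.

    The window's C+G fraction scaled by the promoter's total (C+G)%, so the
    result lies in ``[0, cg_total]``.
    """
    if window_countable < 1:
        raise ValueError("window has no countable bases")
    if not 0.0 <= cg_total <= 100.0:
        raise ValueError("cg_total must be a percentage in [0, 100]")
    return cg_total / window_countable * window_cg


def window_profile(record: PromoterRecord, params: WindowParams = WindowParams()) -> WindowProfile:
    """Profile a promoter: one (relative CG%, KIC%) pair per sliding window.

    Windows containing ``N`` are skipped (they contribute no pattern line);
    the skipped count is reported on the profile.  ``cg_total`` is computed
    over the whole sequence with ``N`` excluded from the base counts.
    """
    L = len(record.sequence)
    W = params.window_size
    count = n_windows(L, params)
    if count == 0:
        raise ValueError(
            f"record {record.id!r}: sequence length {L} admits no window "
            f"(needs length > window_size={W})"
        )
    codes = encode(record.sequence)
    cg_total = cg_percent_total(record.sequence)
    starts = np.arange(count) * params.step

    # Per-lag positionwise match indicators over the whole sequence; window
    # sums then come from prefix sums, one O(L) pass per lag.
    match_counts: list[np.ndarray] = []
    for u in range(1, W):
        m = (codes[:-u] == codes[u:]).astype(np.int64)
        csum = np.concatenate(([0], np.cumsum(m)))
        if params.mode == "full":
            hi, lo = starts + W - u, starts
        else:
            hi, lo = starts + max(W - 1 - u, 0), starts
            hi = np.maximum(hi, lo)
        match_counts.append(csum[hi] - csum[lo])
    kic_vals = _kic_from_counts(match_counts, W, params.mode)

    is_n = (codes == _N_CODE).astype(np.int64)
    n_csum = np.concatenate(([0], np.cumsum(is_n)))
    n_in_window = n_csum[starts + W] - n_csum[starts]
    keep = n_in_window == 0

    is_cg = ((codes == _CODE["C"]) | (codes == _CODE["G"])).astype(np.int64)
    cg_csum = np.concatenate(([0], np.cumsum(is_cg)))
    cg_in_window = cg_csum[starts + W] - cg_csum[starts]
    cg_vals = cg_total / W * cg_in_window  # kept windows have W countable bases

    return WindowProfile(
        promoter_id=record.id,
        params=params,
        cg_values=cg_vals[keep],
        kic_values=kic_vals[keep],
        cg_total=cg_total,
        window_starts=starts[keep],
        n_skipped=int(np.count_nonzero(~keep)),
    )


def profile_table(profile: WindowProfile):
    """Profile as a DataFrame: promoter_id, window_start (1-based), cg_relative, kic."""
    import pandas as pd

    return pd.DataFrame(
        {
            "promoter_id": profile.promoter_id,
            "window_start": profile.window_starts + 1,
            "cg_relative": profile.cg_values,
            "kic": profile.kic_values,
        }
    )
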