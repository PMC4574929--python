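"""Independent brute-force oracles used by the tests.

These deliberately use naive string operations and explicit loops, staying
independent of the vectorized production code paths they check.
"""

from __future__ import annotations


def kic_brute_force(window: str, mode: str = "full") -> float:
    """Literal transcription of the self-coincidence recipe.

    ``A`` has 1-based positions 1..L and ``N = L - 1`` shifts.  For shift u,
    ``B`` is the suffix of A starting at position u+1 — running to the end of
    A in ``"full"`` mode, and only to position N (dropping the final
    character; the empty final suffix contributes nothing) in ``"literal"``
    mode.  Coincidences are counted positionwise between A and B, each shift
    contributes ``C / len(B) * 100``, and the accumulated total is divided by
    N and rounded to two decimals.
    """
    A = window
    N = len(A) - 1
    total = 0.0
    for u in range(1, N + 1):
        if mode == "full":
            B = A[u:]
        else:
            B = A[u:N]
        if not B:
            continue
        C = 0
        for i in range(len(B)):
            if A[i] == B[i]:
                C += 1
        total += C / len(B) * 100.0
    return round(total / N, 2)


def cg_total_brute_force(sequence: str) -> float:
    counted = [b for b in sequence if b in "ACGT"]
    return 100.0 / len(counted) * sum(1 for b in counted if b in "CG")
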