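"""Synthetic promoter generation with controlled compositional structure.

Promoter cohorts separate on two coupled axes: total (C+G)% and the Kappa
Index of Coincidence.  The generator emulates the archetypes that drive that
separation, plus their mixture:

``at_compact``
    AT-rich promoters carrying short poly(dA)/poly(dT) tracts in tandem —
    the low-CG end of the promoter landscape (T1D-like).
``cg_rich``
    CG-rich promoters with short poly(dC)/poly(dG) tracts, CpG-repeat
    stretches and a strand-skewed background — the high-CG, high-KIC end
    (T2D-like).
``intermediate``
    A mixture sitting between the two clouds on both axes (IDM-like).
``uniform``
    An i.i.d. equal-frequency null (KIC about 25, CG about 50).

The background is a first-order chain whose stationary base composition is
pinned to the requested values (``at_fraction`` for A+T, ``base_skew`` for
the within-pair A:T and G:C imbalance) by a small eigenvector fixed-point
calibration, with the C -> G transition up-weighted by ``cpg_boost``.  Short
homopolymer tracts (1-3 tandem blocks per event) and CG-dinucleotide repeat
stretches are then written over the background, preserving length.  For a
self-coincidence statistic the controlling quantity is the within-window
base-composition concentration: skewing the background and adding repeat
stretches raises KIC, which is how ``cg_rich`` earns its higher values.

Everything is reproducible from a single seed; panel generation derives
child seeds deterministically from one master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd

from .sequence_io import PromoterPanel, PromoterRecord

__all__ = [
    "ArchetypeSpec",
    "ARCHETYPES",
    "archetype",
    "generate_promoter",
    "generate_panel",
    "default_panel_spec",
    "truth_table",
]

_BASES = np.array(list("ACGT"))
_IDX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class ArchetypeSpec:
    """Parameters of one promoter archetype.

    ``at_fraction`` is the target A+T proportion of the background;
    ``base_skew`` shifts the within-pair balance (A over T and G over C), so
    composition stays at ``at_fraction`` while single-base concentration —
    and with it the KIC baseline — rises.  ``tract_density`` is the expected
    number of homopolymer tract events per 100 nt; each event writes 1-3
    tandem blocks with lengths from ``tract_length_range`` (inclusive) and
    bases from ``tract_alphabet``.  ``str_density`` controls CG-dinucleotide
    repeat stretches (lengths from ``str_length_range``), the CpG-dense
    microsatellite-like element of CG-rich promoters.  ``cpg_boost``
    multiplies the C -> G transition probability of the background chain.
    """

    name: str
    at_fraction: float = 0.5
    length: int = 500
    base_skew: float = 0.0
    cpg_boost: float = 1.0
    tract_density: float = 0.0
    tract_length_range: tuple[int, int] = (3, 6)
    tract_alphabet: str = "ACGT"
    str_density: float = 0.0
    str_length_range: tuple[int, int] = (8, 14)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length < 31:
            raise ValueError("length must be at least window_size + 1 = 31")
        if not 0.0 <= self.at_fraction <= 1.0:
            raise ValueError("at_fraction must lie in [0, 1]")
        if not -1.0 < self.base_skew < 1.0:
            raise ValueError("base_skew must lie in (-1, 1)")
        for lo, hi in (self.tract_length_range, self.str_length_range):
            if not (1 <= lo <= hi):
                raise ValueError("length ranges must satisfy 1 <= min <= max")
        if self.tract_density < 0 or self.str_density < 0:
            raise ValueError("densities must be non-negative")
        if self.cpg_boost <= 0:
            raise ValueError("cpg_boost must be positive")
        if not set(self.tract_alphabet) <= set("ACGT") or not self.tract_alphabet:
            raise ValueError("tract_alphabet must be a non-empty subset of ACGT")


#: Archetype defaults: the tuning constants that place synthetic group means
#: near the observed cohort contrasts (an AT-rich group around KIC 31 / CG 26
#: against a CG-rich group around KIC 35 / CG 54 — a four-point KIC gap and a
#: nearly thirty-point CG gap, with the intermediate archetype between the
#: two clouds on both axes).  See docs/methods.md for the calibration notes.
ARCHETYPES: dict[str, ArchetypeSpec] = {
    "at_compact": ArchetypeSpec(
        name="at_compact",
        at_fraction=0.73,
        tract_density=0.6,
        tract_length_range=(3, 6),
        tract_alphabet="AT",
    ),
    "cg_rich": ArchetypeSpec(
        name="cg_rich",
        at_fraction=0.56,
        base_skew=0.72,
        cpg_boost=3.0,
        tract_density=0.8,
        tract_length_range=(4, 8),
        tract_alphabet="CG",
        str_density=1.1,
    ),
    "intermediate": ArchetypeSpec(
        name="intermediate",
        at_fraction=0.66,
        base_skew=0.58,
        cpg_boost=2.0,
        tract_density=0.7,
        tract_length_range=(4, 7),
        tract_alphabet="CG",
        str_density=0.5,
    ),
    "uniform": ArchetypeSpec(name="uniform", at_fraction=0.5),
}


def archetype(name: str, **overrides) -> ArchetypeSpec:
    """Fetch an archetype's default spec, optionally overriding fields."""
    if name not in ARCHETYPES:
        raise ValueError(f"unknown archetype {name!r}; known: {sorted(ARCHETYPES)}")
    return replace(ARCHETYPES[name], **overrides)


def _target_composition(at_fraction: float, base_skew: float) -> np.ndarray:
    at, cg = at_fraction, 1.0 - at_fraction
    return np.array(
        [
            at * (1 + base_skew) / 2,  # A
            cg * (1 - base_skew) / 2,  # C
            cg * (1 + base_skew) / 2,  # G
            at * (1 - base_skew) / 2,  # T
        ]
    )


def _chain(p_in: np.ndarray, cpg_boost: float) -> np.ndarray:
    T = np.tile(p_in, (4, 1)).astype(float)
    T[_IDX["C"], _IDX["G"]] *= cpg_boost
    return T / T.sum(axis=1, keepdims=True)


def _stationary(T: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eig(T.T)
    pi = np.abs(np.real(vecs[:, np.argmax(np.real(vals))]))
    return pi / pi.sum()


@lru_cache(maxsize=64)
def _calibrated_chain(at_fraction: float, base_skew: float, cpg_boost: float) -> tuple:
    """First-order chain whose stationary composition matches the target
    despite the CpG boost, found by a multiplicative fixed-point iteration."""
    target = _target_composition(at_fraction, base_skew)
    p_in = target.copy()
    for _ in range(40):
        T = _chain(p_in, cpg_boost)
        observed = _stationary(T)
        if np.max(np.abs(observed - target)) < 1e-4:
            break
        p_in = np.clip(p_in * (target / np.clip(observed, 1e-9, None)) ** 0.8, 1e-9, None)
        p_in /= p_in.sum()
    return tuple(map(tuple, _chain(p_in, cpg_boost))), tuple(target)


def generate_promoter(spec: ArchetypeSpec) -> PromoterRecord:
    """Generate one promoter of exactly ``spec.length`` nt from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    T, p0 = _calibrated_chain(spec.at_fraction, spec.base_skew, spec.cpg_boost)
    cum = np.cumsum(np.array(T), axis=1)
    seq = np.empty(spec.length, dtype=np.int64)
    seq[0] = rng.choice(4, p=np.array(p0))
    u = rng.random(spec.length)
    for i in range(1, spec.length):
        seq[i] = np.searchsorted(cum[seq[i - 1]], u[i])

    # Homopolymer tract events: 1-3 tandem blocks, alternating bases.
    lo, hi = spec.tract_length_range
    alphabet = [_IDX[b] for b in spec.tract_alphabet]
    for _ in range(rng.poisson(spec.tract_density * spec.length / 100.0)):
        pos = int(rng.integers(0, spec.length))
        prev_base = None
        for _block in range(int(rng.integers(1, 4))):
            tract_len = int(rng.integers(lo, hi + 1))
            choices = [b for b in alphabet if b != prev_base] or alphabet
            base = int(rng.choice(choices))
            end = min(pos + tract_len, spec.length)
            seq[pos:end] = base
            pos, prev_base = end, base
            if pos >= spec.length:
                break

    # CG-dinucleotide repeat stretches (CpG-dense microsatellites).
    slo, shi = spec.str_length_range
    for _ in range(rng.poisson(spec.str_density * spec.length / 100.0)):
        pos = int(rng.integers(0, spec.length))
        end = min(pos + int(rng.integers(slo, shi + 1)), spec.length)
        pattern = [_IDX["C"], _IDX["G"]] if rng.random() < 0.5 else [_IDX["G"], _IDX["C"]]
        seq[pos:end] = np.resize(pattern, end - pos)

    return PromoterRecord(
        id=f"{spec.name}_{spec.seed}",
        sequence="".join(_BASES[seq]),
        phenotype="UNLABELED",
        source=f"synthetic:{spec.name}",
    )


def generate_panel(
    group_specs: Mapping[str, tuple[ArchetypeSpec, int]],
    seed: int,
) -> PromoterPanel:
    """Generate a labeled panel; child seeds derive from the master seed.

    ``group_specs`` maps a phenotype label (e.g. ``"T1D"``) to an archetype
    spec and a promoter count.  A group may also map to a list of
    ``(spec, count)`` pairs, which lets a group mix archetypes (e.g. core
    promoters plus planted intermediates) while keeping one phenotype label;
    the ground-truth archetype of every record stays in its ``source`` tag.
    The same master seed always yields the same panel.
    """
    normalized: dict[str, list[tuple[ArchetypeSpec, int]]] = {}
    for label, entry in group_specs.items():
        parts = entry if isinstance(entry, list) else [entry]
        for spec, count in parts:
            if count < 1:
                raise ValueError(f"group {label!r} needs positive counts")
        normalized[label] = list(parts)

    total = sum(c for parts in normalized.values() for _, c in parts)
    child_seeds = iter(
        int(s) & 0x7FFFFFFF for s in np.random.SeedSequence(seed).generate_state(total)
    )
    records: list[PromoterRecord] = []
    groups: dict[str, list[str]] = {}
    for label, parts in normalized.items():
        i = 0
        for spec, count in parts:
            for _ in range(count):
                i += 1
                child = replace(spec, seed=next(child_seeds))
                rec = generate_promoter(child)
                phenotype = label if label in ("T1D", "T2D", "IDM", "BACKGROUND") else "UNLABELED"
                rec = PromoterRecord(
                    id=f"{label}_{i:02d}",
                    sequence=rec.sequence,
                    gene=None,
                    phenotype=phenotype,
                    source=rec.source,
                )
                records.append(rec)
                if phenotype != "UNLABELED":
                    groups.setdefault(phenotype, []).append(rec.id)
    return PromoterPanel(records=records, groups=groups)


def default_panel_spec(
    n_t1d: int = 15, n_t2d: int = 16
) -> dict[str, tuple[ArchetypeSpec, int]]:
    """The default two-group panel: AT-compact T1D-like vs CG-rich T2D-like."""
    return {
        "T1D": (archetype("at_compact"), n_t1d),
        "T2D": (archetype("cg_rich"), n_t2d),
    }


def truth_table(panel: PromoterPanel) -> pd.DataFrame:
    """Ground-truth table (id, archetype, group) for a generated panel."""
    return pd.DataFrame(
        {
            "id": [r.id for r in panel.records],
            "archetype": [r.source.split(":", 1)[-1] for r in panel.records],
            "group": [r.phenotype for r in panel.records],
        }
    )
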