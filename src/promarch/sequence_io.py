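"""Reading and validating promoter sequences and panel configurations.

Promoter sequences arrive as plain FASTA (EPD-style extracts of the 500 bp
region upstream of a gene, one entry per promoter).  A *panel* attaches gene
symbols and phenotype labels (e.g. T1D / T2D) to a subset of those records via
a small tabular config, so cohort-level statistics can be computed downstream.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PHENOTYPES",
    "PromoterRecord",
    "PromoterPanel",
    "read_fasta",
    "write_fasta",
    "load_panel",
    "read_panel_config",
]

#: Recognised phenotype labels.  ``IDM`` is the intermediary phenotype;
#: ``BACKGROUND`` marks genome-wide reference promoters.
PHENOTYPES = ("T1D", "T2D", "IDM", "BACKGROUND", "UNLABELED")

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class PromoterRecord:
    """One named promoter sequence.

    Parameters
    ----------
    id:
        Unique identifier (FASTA header token before the first whitespace).
    sequence:
        Upper-case DNA over the alphabet ``{A, C, G, T, N}``.
    gene:
        Optional gene symbol (e.g. ``"INS"``).
    phenotype:
        One of :data:`PHENOTYPES`; defaults to ``"UNLABELED"``.
    source:
        Free-text provenance tag (``"EPD"``, ``"HomoloGene"``, ``"synthetic"`` ...).
    """

    id: str
    sequence: str
    gene: str | None = None
    phenotype: str = "UNLABELED"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("promoter record requires a non-empty id")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence is empty")
        seq = self.sequence.upper()
        for pos, base in enumerate(seq, start=1):
            if base not in _VALID_BASES:
                raise ValueError(
                    f"record {self.id!r}: illegal character {base!r} at position {pos}"
                )
        object.__setattr__(self, "sequence", seq)
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"record {self.id!r}: unknown phenotype {self.phenotype!r}; "
                f"expected one of {PHENOTYPES}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PromoterPanel:
    """An ordered collection of promoter records with a phenotype index."""

    records: list[PromoterRecord]
    groups: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate promoter id {dup!r} in panel")
        known = set(ids)
        seen: set[str] = set()
        for label, members in self.groups.items():
            for pid in members:
                if pid not in known:
                    raise ValueError(f"group {label!r} references unknown id {pid!r}")
                if pid in seen:
                    raise ValueError(f"id {pid!r} assigned to more than one phenotype")
                seen.add(pid)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, promoter_id: str) -> PromoterRecord:
        for rec in self.records:
            if rec.id == promoter_id:
                return rec
        raise KeyError(promoter_id)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def group(self, phenotype: str) -> list[PromoterRecord]:
        """Records assigned to one phenotype group, in panel order."""
        members = set(self.groups.get(phenotype, ()))
        return [r for r in self.records if r.id in members]


def read_fasta(path: str | Path) -> list[PromoterRecord]:
    """Read promoter records from a FASTA file.

    Accepts multi-line bodies, CRLF line endings and blank lines.  Sequences
    are upper-cased; characters outside ``{A,C,G,T,N}`` are rejected with
    their 1-based position.  All records come back ``UNLABELED``.
    """
    path = Path(path)
    records: list[PromoterRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ValueError(f"duplicate sequence id {entry.id!r} in {path}")
        seen.add(entry.id)
        records.append(PromoterRecord(id=entry.id, sequence=str(entry.seq)))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_fasta(records: Iterable[PromoterRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA, one entry per record, in order."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.gene or "")
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def read_panel_config(path: str | Path) -> pd.DataFrame:
    """Read a panel config table (TSV or CSV) with columns id, gene, phenotype."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, dtype=str, comment="#").fillna("")
    missing = {"id", "gene", "phenotype"} - set(table.columns)
    if missing:
        raise ValueError(f"panel config {path} lacks columns: {sorted(missing)}")
    return table


def load_panel(fasta_path: str | Path, panel_config: str | Path | None = None) -> PromoterPanel:
    """Read a FASTA and attach gene symbols / phenotype labels from a config.

    Every id referenced by the config must exist in the FASTA; an id may be
    assigned at most one phenotype.  Records not mentioned by the config stay
    ``UNLABELED`` and belong to no group.  With no config, all records are
    ``UNLABELED``.
    """
    records = read_fasta(fasta_path)
    if panel_config is None:
        return PromoterPanel(records=records)

    table = read_panel_config(panel_config)
    by_id = {r.id: r for r in records}
    assigned: dict[str, tuple[str, str]] = {}
    for row in table.itertuples(index=False):
        pid = str(row.id)
        if pid not in by_id:
            raise ValueError(f"panel config references unknown id {pid!r}")
        phenotype = str(row.phenotype) or "UNLABELED"
        if pid in assigned and assigned[pid][1] != phenotype:
            raise ValueError(f"id {pid!r} assigned two phenotypes")
        assigned[pid] = (str(row.gene), phenotype)

    out: list[PromoterRecord] = []
    groups: dict[str, list[str]] = {}
    for rec in records:
        if rec.id in assigned:
            gene, phenotype = assigned[rec.id]
            rec = replace(rec, gene=gene or None, phenotype=phenotype)
            if phenotype != "UNLABELED":
                groups.setdefault(phenotype, []).append(rec.id)
        out.append(rec)
    return PromoterPanel(records=out, groups=groups)


def records_from_strings(text: str) -> list[PromoterRecord]:
    """Parse FASTA text held in memory (convenience for tests and docs)."""
    entries = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not entries:
        raise ValueError("no sequences found in FASTA text")
    return [PromoterRecord(id=e.id, sequence=str(e.seq)) for e in entries]
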