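"""Sequence and site-table I/O.

Reads protein FASTA files and tab-separated site-annotation tables,
extracts fixed-width peptide windows centred on candidate carbonylation
residues (K, P, R, T), and writes prediction tables.

Conventions
-----------
* Positions are 1-based in every file read or written; internal Python
  indexing is 0-based and never leaks into I/O.
* Sequences are uppercased on input; any character outside the 20
  standard amino-acid letters is replaced by ``'X'`` (with a logged
  warning) so that downstream encoding can skip it.
* Windows at sequence termini are truncated to the available residues,
  never padded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in the fixed alphabetical order used
#: throughout the package (also the DR feature ordering).
STANDARD_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

#: Placeholder for any non-standard residue (B, J, O, U, Z, *, ...).
UNKNOWN_RESIDUE = "X"

#: Residue types susceptible to carbonylation.
CANDIDATE_RESIDUES = frozenset("KPRT")

_STANDARD_SET = frozenset(STANDARD_RESIDUES)

SITE_COLUMNS = ["protein_id", "position", "residue", "label"]
PREDICTION_COLUMNS = ["protein_id", "position", "residue", "score", "call"]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with its identifier.

    The sequence is uppercase and restricted to the 20 standard
    residues plus ``'X'``.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for protein {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteAnnotation:
    """A candidate site: residue `residue` at 1-based `position` of
    protein `protein_id`, with binary carbonylation `label`
    (``None`` for unlabeled prediction candidates)."""

    protein_id: str
    position: int
    residue: str
    label: int | None = None


@dataclass(frozen=True)
class SiteWindow:
    """A peptide window of up to ``2*half_width + 1`` residues centred
    on an annotated site; truncated (not padded) at termini."""

    protein_id: str
    position: int
    residue: str
    label: int | None
    window_sequence: str
    half_width: int


def normalize_sequence(raw: str, record_id: str = "?") -> str:
    """Uppercase `raw` and replace non-standard residues by 'X'."""
    seq = raw.upper()
    out = []
    for i, ch in enumerate(seq):
        if ch in _STANDARD_SET:
            out.append(ch)
        else:
            logger.warning(
                "protein %s: replacing non-standard residue %r at position %d with 'X'",
                record_id, ch, i + 1,
            )
            out.append(UNKNOWN_RESIDUE)
    return "".join(out)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Raises
    ------
    ValueError
        If the file contains no records or a duplicate identifier.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id in FASTA: {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, normalize_sequence(str(rec.seq), rec.id)))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _protein_index(proteins: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {p.id: p for p in proteins}


def read_sites(path: str | Path, proteins: Sequence[ProteinRecord]) -> list[SiteAnnotation]:
    """Read a site-annotation TSV and validate each row against its protein.

    The table must have columns ``protein_id``, ``position`` (1-based),
    ``residue`` and ``label`` (0/1). A row whose position is out of range,
    whose protein is unknown, or whose stated residue disagrees with the
    sequence raises a row-numbered ``ValueError``.
    """
    table = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "residue": str})
    missing = [c for c in SITE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"site table {path} lacks columns: {missing}")
    index = _protein_index(proteins)
    sites: list[SiteAnnotation] = []
    for row_no, row in enumerate(table.itertuples(index=False), start=2):  # 1 = header
        pid = row.protein_id
        if pid not in index:
            raise ValueError(f"row {row_no}: unknown protein_id {pid!r}")
        seq = index[pid].sequence
        pos = int(row.position)
        if not 1 <= pos <= len(seq):
            raise ValueError(
                f"row {row_no}: position out of range ({pos} not in 1..{len(seq)})"
            )
        residue = str(row.residue).upper()
        found = seq[pos - 1]
        if found != residue:
            raise ValueError(
                f"row {row_no}: residue mismatch: found {found}, annotation says {residue}"
            )
        label = int(row.label)
        if label not in (0, 1):
            raise ValueError(f"row {row_no}: label must be 0 or 1, got {row.label!r}")
        sites.append(SiteAnnotation(pid, pos, residue, label))
    return sites


def extract_windows(
    proteins: Sequence[ProteinRecord],
    sites: Sequence[SiteAnnotation],
    half_width: int = 10,
) -> list[SiteWindow]:
    """Cut a peptide window of ``half_width`` residues either side of
    each annotated site.

    Interior sites yield windows of length ``2*half_width + 1`` with the
    annotated residue exactly at the centre; sites near a terminus yield
    shorter, truncated windows.
    """
    if half_width < 1:
        raise ValueError(f"half_width must be >= 1, got {half_width}")
    index = _protein_index(proteins)
    windows = []
    for site in sites:
        seq = index[site.protein_id].sequence
        i = site.position - 1
        lo = max(0, i - half_width)
        hi = min(len(seq), i + half_width + 1)
        windows.append(
            SiteWindow(
                protein_id=site.protein_id,
                position=site.position,
                residue=site.residue,
                label=site.label,
                window_sequence=seq[lo:hi],
                half_width=half_width,
            )
        )
    return windows


def scan_candidate_sites(protein: ProteinRecord, residue: str) -> list[SiteAnnotation]:
    """Return one unlabeled annotation per occurrence of `residue`
    (one of K/P/R/T) in the protein, positions ascending."""
    if residue not in CANDIDATE_RESIDUES:
        raise ValueError(f"residue must be one of K, P, R, T; got {residue!r}")
    return [
        SiteAnnotation(protein.id, i + 1, residue, None)
        for i, ch in enumerate(protein.sequence)
        if ch == residue
    ]


def write_predictions(table: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction table (protein_id, position, residue, score, call)."""
    table.loc[:, PREDICTION_COLUMNS].to_csv(path, sep="\t", index=False)
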