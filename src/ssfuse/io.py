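"""Readers and writers for the package's interchange formats.

Sequences travel as FASTA (parsed with Biopython).  Evidence travels as a
plain tab-separated table with a header line::

    protein_id  method  cys_a  cys_b  belief  [extra metadata columns...]

Extra columns (``precursor_mass``, ``pp2``, ``divergence``,
``n_best_matches``) are preserved in a side table so that discounting can
consume them.  Topology/bond-list tables use the same layout without the
belief column.  Fused results are written as::

    protein_id  rule  cys_a  cys_b  fused_belief
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from Bio import SeqIO

from .core import BondHypothesis, Evidence, EvidenceSet, Protein, Topology, bond

EVIDENCE_COLUMNS = ("protein_id", "method", "cys_a", "cys_b", "belief")

_METADATA_COLUMNS = ("precursor_mass", "pp2", "divergence", "n_best_matches")


class EvidenceFormatError(ValueError):
    """Malformed evidence table (bad header, value, or duplicate row)."""


def read_fasta(path: str | os.PathLike) -> list[Protein]:
    """Read a FASTA file into :class:`Protein` records.

    Cysteine positions are derived by scanning each sequence for 'C'.
    """
    proteins = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            proteins.append(Protein(id=rec.id, sequence=str(rec.seq).upper()))
    except ValueError as exc:  # Biopython signals malformed records this way
        raise EvidenceFormatError(f"malformed FASTA in {path}: {exc}") from exc
    return proteins


def write_fasta(proteins: Iterable[Protein], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            seq = p.sequence
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


@dataclass
class EvidenceTable:
    """Parsed evidence file: grouped sets plus per-row source metadata.

    ``metadata`` maps ``(protein_id, method, bond)`` to a dict of the
    optional numeric columns present in the file (used by discounting).
    """

    sets: list[EvidenceSet]
    metadata: dict[tuple[str, str, BondHypothesis], dict[str, float]] = field(
        default_factory=dict
    )

    def for_protein(self, protein_id: str) -> list[EvidenceSet]:
        return [s for s in self.sets if s.protein_id == protein_id]

    def protein_ids(self) -> list[str]:
        seen: list[str] = []
        for s in self.sets:
            if s.protein_id not in seen:
                seen.append(s.protein_id)
        return seen


def read_evidence_table(path: str | os.PathLike) -> list[EvidenceSet]:
    """Read an evidence TSV, returning one EvidenceSet per (protein, method).

    Rows are grouped by (protein_id, method) in file order; bonds are
    canonicalised so cys_a < cys_b.  Beliefs outside [0, 1], self-bonds and
    duplicate (protein, method, bond) rows raise
    :class:`EvidenceFormatError` naming the offending row.
    """
    return read_evidence(path).sets


def read_evidence(path: str | os.PathLike) -> EvidenceTable:
    """Like :func:`read_evidence_table` but also keeps metadata columns."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[: len(EVIDENCE_COLUMNS)] != list(EVIDENCE_COLUMNS):
            raise EvidenceFormatError(
                f"{path}: expected header starting with "
                f"{' '.join(EVIDENCE_COLUMNS)}, got {' '.join(header)}"
            )
        extra_cols = header[len(EVIDENCE_COLUMNS) :]
        groups: dict[tuple[str, str], list[Evidence]] = {}
        metadata: dict[tuple[str, str, BondHypothesis], dict[str, float]] = {}
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < len(EVIDENCE_COLUMNS):
                raise EvidenceFormatError(f"{path}:{lineno}: too few columns")
            pid, method, a_s, b_s, belief_s = parts[:5]
            try:
                a, b_pos = int(a_s), int(b_s)
                belief = float(belief_s)
            except ValueError as exc:
                raise EvidenceFormatError(f"{path}:{lineno}: {exc}") from exc
            if a == b_pos:
                raise EvidenceFormatError(
                    f"{path}:{lineno}: cys_a == cys_b ({a}) is not a bond"
                )
            if not 0.0 <= belief <= 1.0:
                raise EvidenceFormatError(
                    f"{path}:{lineno}: belief {belief} outside [0, 1]"
                )
            b = bond(a, b_pos)
            key = (pid, method)
            groups.setdefault(key, [])
            if any(ev.bond == b for ev in groups[key]):
                raise EvidenceFormatError(
                    f"{path}:{lineno}: duplicate bond {b} for ({pid}, {method})"
                )
            groups[key].append(Evidence(bond=b, belief=belief, method=method))
            meta = {
                col: float(val)
                for col, val in zip(extra_cols, parts[5:])
                if val != "" and col in _METADATA_COLUMNS
            }
            if meta:
                metadata[(pid, method, b)] = meta
    sets = [
        EvidenceSet(protein_id=pid, method=method, items=items)
        for (pid, method), items in groups.items()
    ]
    return EvidenceTable(sets=sets, metadata=metadata)


def write_evidence_table(
    sets: Iterable[EvidenceSet],
    path: str | os.PathLike,
    metadata: Mapping[tuple[str, str, BondHypothesis], Mapping[str, float]] | None = None,
) -> None:
    """Write evidence sets (and optional metadata columns) as TSV."""
    metadata = dict(metadata or {})
    extra_cols = sorted({col for meta in metadata.values() for col in meta})
    with open(path, "w") as fh:
        fh.write("\t".join(EVIDENCE_COLUMNS + tuple(extra_cols)) + "\n")
        for s in sets:
            for ev in s.items:
                row = [
                    s.protein_id,
                    s.method,
                    str(ev.bond.cys_a),
                    str(ev.bond.cys_b),
                    repr(ev.belief),
                ]
                meta = metadata.get((s.protein_id, s.method, ev.bond), {})
                row += [repr(meta[c]) if c in meta else "" for c in extra_cols]
                fh.write("\t".join(row) + "\n")


def read_bond_table(path: str | os.PathLike) -> dict[tuple[str, str], list[BondHypothesis]]:
    """Read a bond-list TSV (protein_id, method, cys_a, cys_b) → bonds per
    (protein, method).  Used for known-topology and per-method bond fixtures."""
    out: dict[tuple[str, str], list[BondHypothesis]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:4] != ["protein_id", "method", "cys_a", "cys_b"]:
            raise EvidenceFormatError(f"{path}: bad bond-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            pid, method, a_s, b_s = line.split("\t")[:4]
            out.setdefault((pid, method), []).append(bond(int(a_s), int(b_s)))
    return out


def write_results_table(
    rows: Iterable[tuple[str, str, BondHypothesis, float]],
    path: str | os.PathLike,
) -> None:
    """Write fused per-bond results: (protein_id, rule, bond, fused_belief).

    Beliefs are written rounded to two decimals, the package's report
    precision; upstream values stay full-precision in memory.
    """
    with open(path, "w") as fh:
        fh.write("protein_id\trule\tcys_a\tcys_b\tfused_belief\n")
        for pid, rule, b, score in rows:
            fh.write(f"{pid}\t{rule}\t{b.cys_a}\t{b.cys_b}\t{score:.2f}\n")


def write_topology_table(
    topologies: Mapping[str, Topology], path: str | os.PathLike, method: str = "truth"
) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tmethod\tcys_a\tcys_b\n")
        for pid, topo in topologies.items():
            for b in topo:
                fh.write(f"{pid}\t{method}\t{b.cys_a}\t{b.cys_b}\n")
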