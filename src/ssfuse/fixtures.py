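"""Packaged fixture data: the published case-study tables as files.

The fixtures encode, verbatim, the printed inputs and outputs of the
glycosyltransferase study this package reproduces: the two-method
conflicting-evidence example on the trypsin-inhibitor 1G6X, the
per-method baseline bond sets for the seven glycosyltransferases, the
beta-1,4-GalT case-study evidence, the fused (Shafer-rule) bond sets, and
the MassMatrix-combination bond sets.  The 1G6X FASTA and the CSP
reference database are synthetic stand-ins (real sequences and the
439-protein annotated database are not shipped); their cysteine layouts
are what the methods consume.
"""

from __future__ import annotations

from importlib import resources

from .core import BondHypothesis, EvidenceSet, Protein, Topology
from .csp import ReferenceEntry, read_reference_db
from .io import read_bond_table, read_evidence_table, read_fasta

_DATA = resources.files("ssfuse") / "data"


def _path(name: str) -> str:
    return str(_DATA / name)


def example1_evidence() -> dict[str, EvidenceSet]:
    """The two conflicting evidence sets (M1, M2) for 1G6X, keyed by method."""
    return {s.method: s for s in read_evidence_table(_path("example1_evidence.tsv"))}


def example1_protein() -> Protein:
    """Synthetic 58-residue stand-in with cysteines at 5/14/31/38/51/55."""
    return read_fasta(_path("example1_synthetic.fasta"))[0]


def table2_bonds() -> dict[tuple[str, str], list[BondHypothesis]]:
    """Baseline per-method bond sets plus known linkages, 7 proteins.

    Methods: ``known``, ``MS2DB+``, ``SVM``, ``CSP``.
    """
    return read_bond_table(_path("table2_bonds.tsv"))


def known_topologies() -> dict[str, Topology]:
    """The known S-S linkages of the seven study proteins."""
    bonds = table2_bonds()
    return {
        pid: Topology(frozenset(bs))
        for (pid, method), bs in bonds.items()
        if method == "known"
    }


def method_bonds(method: str) -> dict[str, list[BondHypothesis]]:
    """One method's reported bonds per protein, from the baseline table."""
    return {
        pid: bs for (pid, m), bs in table2_bonds().items() if m == method
    }


def table4_evidence() -> list[EvidenceSet]:
    """Case-study initial connectivity for beta-1,4-GalT (MS, SVM, CSP)."""
    return read_evidence_table(_path("table4_evidence.tsv"))


def table5_fused() -> list[EvidenceSet]:
    """Fused bond sets and beliefs from the three-method Shafer combination."""
    return read_evidence_table(_path("table5_fused.tsv"))


def table8_bonds() -> dict[tuple[str, str], list[BondHypothesis]]:
    """MassMatrix-combination bond sets (methods: ``massmatrix``,
    ``dempster_campos_shafer``, ``yager``)."""
    return read_bond_table(_path("table8_bonds.tsv"))


def reference_db() -> list[ReferenceEntry]:
    """Small synthetic CSP reference database (12 annotated entries)."""
    return read_reference_db(_path("synthetic_refdb.tsv"))
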