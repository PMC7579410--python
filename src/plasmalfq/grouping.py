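"""In-silico tryptic digestion and majority-protein-group assembly.

Protein inference from shared peptides collapses proteins that cannot be
distinguished by their detected peptides into "majority protein groups":
a candidate protein joins a group when at least half of its own peptides are
shared with the group's lead protein.  The sharing denominator is the
candidate's own peptide count (asymmetric, majority-style semantics), which
guarantees that a protein whose peptide set is nested inside another's always
co-groups with it — the behaviour protein-group tools exhibit for
indistinguishable isoforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._rand import child_rng
from .datatypes import ProteinRecord

__all__ = [
    "tryptic_digest",
    "PeptideIndex",
    "build_peptide_index",
    "MajorityProteinGroup",
    "assemble_groups",
]


def tryptic_digest(
    sequence: str,
    missed_cleavages: int = 2,
    min_len: int = 7,
    max_len: int = 35,
) -> set[str]:
    """All tryptic peptides of a sequence as a set.

    Trypsin cleaves C-terminal to K or R except when the next residue is P.
    Peptides spanning up to ``missed_cleavages`` internal cleavage sites are
    generated, then filtered to ``[min_len, max_len]``.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    if not 1 <= min_len <= max_len:
        raise ValueError("need 1 <= min_len <= max_len")
    seq = sequence.upper()
    # cut points: position after each K/R not followed by P, plus both ends
    cuts = [0]
    for i, aa in enumerate(seq[:-1]):
        if aa in "KR" and seq[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(seq))
    peptides: set[str] = set()
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + missed_cleavages, len(cuts))):
            pep = seq[cuts[a]: cuts[b]]
            if min_len <= len(pep) <= max_len:
                peptides.add(pep)
    return peptides


@dataclass
class PeptideIndex:
    """Bipartite map between detected peptides and the proteins carrying them."""

    peptide_to_proteins: dict[str, set[str]]
    protein_to_peptides: dict[str, set[str]]
    empty_proteins: list[str] = field(default_factory=list)

    def validate(self) -> None:
        for pep, accs in self.peptide_to_proteins.items():
            for acc in accs:
                if pep not in self.protein_to_peptides.get(acc, set()):
                    raise ValueError(f"index inconsistent at peptide {pep!r} / protein {acc!r}")
        for acc, peps in self.protein_to_peptides.items():
            for pep in peps:
                if acc not in self.peptide_to_proteins.get(pep, set()):
                    raise ValueError(f"index inconsistent at protein {acc!r} / peptide {pep!r}")

    @classmethod
    def from_protein_map(cls, protein_to_peptides: Mapping[str, Iterable[str]]) -> "PeptideIndex":
        p2p = {acc: set(peps) for acc, peps in protein_to_peptides.items()}
        inv: dict[str, set[str]] = {}
        for acc, peps in p2p.items():
            for pep in peps:
                inv.setdefault(pep, set()).add(acc)
        return cls(peptide_to_proteins=inv, protein_to_peptides=p2p,
                   empty_proteins=[a for a, s in p2p.items() if not s])


def build_peptide_index(
    proteins: Sequence[ProteinRecord],
    missed_cleavages: int = 2,
    min_len: int = 7,
    max_len: int = 35,
    detectability: float = 1.0,
    seed: int = 0,
) -> PeptideIndex:
    """Digest every non-decoy, non-contaminant protein and subsample peptides.

    Each distinct peptide is retained with probability ``detectability``;
    retention is decided once per peptide (from the seed and the peptide
    string), so a shared peptide is kept or dropped atomically for all its
    carrier proteins.  Proteins losing all peptides stay in the index with an
    empty set and are listed in ``empty_proteins``.
    """
    if not 0.0 < detectability <= 1.0:
        raise ValueError("detectability must be in (0, 1]")
    digests = {
        rec.accession: tryptic_digest(rec.sequence, missed_cleavages, min_len, max_len)
        for rec in proteins
        if not (rec.is_decoy or rec.is_contaminant)
    }
    if detectability < 1.0:
        all_peps = set().union(*digests.values()) if digests else set()
        kept = {
            pep
            for pep in all_peps
            if child_rng(seed, "detect", pep).random() < detectability
        }
        digests = {acc: peps & kept for acc, peps in digests.items()}
    return PeptideIndex.from_protein_map(digests)


@dataclass
class MajorityProteinGroup:
    group_id: int
    lead: str
    members: set[str]
    group_peptides: set[str]

    def __post_init__(self) -> None:
        if self.lead not in self.members:
            raise ValueError("lead must be a member of its group")


def assemble_groups(
    index: PeptideIndex, sharing_threshold: float = 0.5
) -> list[MajorityProteinGroup]:
    """Partition proteins into majority groups under the shared-peptide rule.

    Greedy seeding: proteins are ranked by (descending peptide count,
    ascending accession); the top unassigned protein seeds a group as lead,
    and any unassigned protein P joins when
    ``|pep(P) & pep(lead)| / |pep(P)| >= sharing_threshold``.
    Membership is tested against the lead only, and the deterministic ranking
    makes the output independent of input order.  Proteins with empty peptide
    sets are excluded (they remain listed in ``index.empty_proteins``).
    Groups are returned ordered by descending group-peptide count.
    """
    if not 0.0 < sharing_threshold <= 1.0:
        raise ValueError("sharing_threshold must be in (0, 1]")
    peps = index.protein_to_peptides
    ranked = sorted(
        (acc for acc, s in peps.items() if s),
        key=lambda acc: (-len(peps[acc]), acc),
    )
    unassigned = dict.fromkeys(ranked)  # insertion-ordered set
    groups: list[MajorityProteinGroup] = []
    while unassigned:
        lead = next(iter(unassigned))
        lead_peps = peps[lead]
        members = {lead}
        for acc in list(unassigned):
            if acc == lead:
                continue
            own = peps[acc]
            if len(own & lead_peps) / len(own) >= sharing_threshold:
                members.add(acc)
        for acc in members:
            del unassigned[acc]
        union = set().union(*(peps[m] for m in members))
        groups.append(MajorityProteinGroup(0, lead, members, union))
    groups.sort(key=lambda g: (-len(g.group_peptides), g.lead))
    for i, g in enumerate(groups):
        g.group_id = i + 1
    return groups
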