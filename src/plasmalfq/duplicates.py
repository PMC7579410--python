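"""Duplicated-protein diagnostics relative to protein-group structure.

Salmonid genomes carry thousands of gene pairs retained from the lineage-
specific fourth-round whole-genome duplication (Ss4R); the encoded protein
duplicates (ohnologs/homeologs) share roughly 70-100% amino-acid identity.
This module quantifies, for any proteome and its majority protein groups,
how duplicate pairs distribute across groups:

* scenario i  — a group containing duplicated proteins from distinct genes;
* scenario ii — groups whose members have duplicates only in *other* groups.

Identity is measured on a global alignment trimmed to the shorter protein;
peptide sharing uses the smaller peptide set as denominator, so a nested set
scores 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats

from .datatypes import ProteinRecord
from .grouping import MajorityProteinGroup, PeptideIndex

__all__ = [
    "DuplicatePair",
    "ScenarioSummary",
    "pairwise_identity",
    "shared_peptide_fraction",
    "find_duplicates",
    "classify_scenarios",
    "correlate_identity_sharing",
    "summary_table",
]


@dataclass
class DuplicatePair:
    """One duplicated-protein pair, in canonical accession order."""

    acc_a: str
    acc_b: str
    identity_pct: float
    shared_pct: float | None = None
    same_mpg: bool | None = None
    is_ss4r: bool | None = None

    def __post_init__(self) -> None:
        if self.acc_a >= self.acc_b:
            raise ValueError("pair must satisfy acc_a < acc_b")
        if not 0.0 <= self.identity_pct <= 100.0:
            raise ValueError("identity_pct out of [0, 100]")
        if self.shared_pct is not None and not 0.0 <= self.shared_pct <= 100.0:
            raise ValueError("shared_pct out of [0, 100]")


@dataclass
class ScenarioSummary:
    n_no_duplicate: int
    n_scenario_i: int
    n_scenario_ii: int

    @property
    def total(self) -> int:
        return self.n_no_duplicate + self.n_scenario_i + self.n_scenario_ii


def _make_aligner(match: float = 1.0, mismatch: float = -1.0,
                  gap_open: float = -10.0, gap_extend: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    aligner: Align.PairwiseAligner | None = None,
) -> float:
    """Percent identity over the global alignment trimmed to the shorter
    protein's aligned span (terminal overhangs of the longer one ignored)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    col_a, col_b = str(aln[0]), str(aln[1])
    short = 0 if len(seq_a) <= len(seq_b) else 1
    cols = col_a if short == 0 else col_b
    first = next(i for i, c in enumerate(cols) if c != "-")
    last = len(cols) - 1 - next(i for i, c in enumerate(reversed(cols)) if c != "-")
    a_trim = col_a[first: last + 1]
    b_trim = col_b[first: last + 1]
    matches = sum(1 for x, y in zip(a_trim, b_trim) if x == y and x != "-")
    return 100.0 * matches / len(a_trim)


def shared_peptide_fraction(pep_a: set[str], pep_b: set[str]) -> float:
    """Percent of peptides shared: 100 * |A n B| / min(|A|, |B|)."""
    if not pep_a and not pep_b:
        raise ValueError("both peptide sets are empty")
    denom = min(len(pep_a), len(pep_b))
    if denom == 0:
        return 0.0
    return 100.0 * len(pep_a & pep_b) / denom


def find_duplicates(
    proteins: Sequence[ProteinRecord],
    identity_cutoff: float = 70.0,
    coverage_cutoff: float = 70.0,
) -> list[DuplicatePair]:
    """All unordered pairs exceeding the identity and mutual-coverage cutoffs.

    Mutual length coverage is ``100 * shorter / longer``; pairs of records
    from the same gene are skipped (isoforms are not duplicates).
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    aligner = _make_aligner()
    pairs: list[DuplicatePair] = []
    for rec_a, rec_b in combinations(proteins, 2):
        if rec_a.gene_id is not None and rec_a.gene_id == rec_b.gene_id:
            continue
        la, lb = len(rec_a.sequence), len(rec_b.sequence)
        coverage = 100.0 * min(la, lb) / max(la, lb)
        if coverage <= coverage_cutoff:
            continue
        ident = pairwise_identity(rec_a.sequence, rec_b.sequence, aligner)
        if ident <= identity_cutoff:
            continue
        a, b = sorted((rec_a.accession, rec_b.accession))
        pairs.append(DuplicatePair(acc_a=a, acc_b=b, identity_pct=ident))
    return pairs


def classify_scenarios(
    groups: Sequence[MajorityProteinGroup],
    pairs: Sequence[DuplicatePair],
    index: PeptideIndex | None = None,
    gene_map: Mapping[str, str] | None = None,
    homeolog_pairs: set[frozenset[str]] | None = None,
    chromosome_map: Mapping[str, str] | None = None,
) -> tuple[ScenarioSummary, list[DuplicatePair]]:
    """Annotate pairs with group/ohnolog flags and count group scenarios.

    A group is scenario i when it holds two members from distinct genes that
    form a duplicate pair; a group whose members' duplicates all live in other
    groups is scenario ii; groups touching no duplicate pair are counted
    separately.  ``is_ss4r`` is set when both chromosomes of a pair form one
    of the configured homeologous chromosome pairings.
    """
    group_of: dict[str, int] = {}
    for g in groups:
        for acc in g.members:
            group_of[acc] = g.group_id
    annotated: list[DuplicatePair] = []
    for p in pairs:
        for acc in (p.acc_a, p.acc_b):
            if acc not in group_of:
                raise ValueError(f"pair references {acc!r}, absent from the groups")
        shared = p.shared_pct
        if shared is None and index is not None:
            shared = shared_peptide_fraction(
                index.protein_to_peptides[p.acc_a], index.protein_to_peptides[p.acc_b]
            )
        is_ss4r = None
        if homeolog_pairs is not None and chromosome_map is not None:
            ca, cb = chromosome_map.get(p.acc_a), chromosome_map.get(p.acc_b)
            is_ss4r = ca is not None and cb is not None and frozenset((ca, cb)) in homeolog_pairs
        annotated.append(
            DuplicatePair(
                acc_a=p.acc_a,
                acc_b=p.acc_b,
                identity_pct=p.identity_pct,
                shared_pct=shared,
                same_mpg=group_of[p.acc_a] == group_of[p.acc_b],
                is_ss4r=is_ss4r,
            )
        )

    scenario_i: set[int] = set()
    touched: set[int] = set()
    for p in annotated:
        ga, gb = group_of[p.acc_a], group_of[p.acc_b]
        touched.update((ga, gb))
        if ga == gb:
            distinct_genes = True
            if gene_map is not None:
                distinct_genes = gene_map.get(p.acc_a) != gene_map.get(p.acc_b)
            if distinct_genes:
                scenario_i.add(ga)
    all_ids = {g.group_id for g in groups}
    scenario_ii = touched - scenario_i
    summary = ScenarioSummary(
        n_no_duplicate=len(all_ids - touched),
        n_scenario_i=len(scenario_i),
        n_scenario_ii=len(scenario_ii),
    )
    return summary, annotated


def correlate_identity_sharing(
    pairs: Sequence[DuplicatePair], stratum: str | None = None
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between identity and peptide
    sharing, optionally within the ``same_mpg`` / ``different_mpg`` stratum."""
    if stratum not in (None, "same_mpg", "different_mpg"):
        raise ValueError(f"unknown stratum {stratum!r}")
    sel = [
        p
        for p in pairs
        if p.shared_pct is not None
        and (
            stratum is None
            or (stratum == "same_mpg") == bool(p.same_mpg)
        )
    ]
    if len(sel) < 3:
        raise ValueError("need at least 3 pairs with shared_pct in the stratum")
    x = np.array([p.identity_pct for p in sel])
    y = np.array([p.shared_pct for p in sel])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in identity or sharing")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def summary_table(pairs: Sequence[DuplicatePair]) -> pd.DataFrame:
    """Mean/SD/range of identity and sharing per (same-group x Ss4R) stratum."""
    rows = []
    for same in (True, False):
        for ss4r in (True, False, None):
            sel = [p for p in pairs if bool(p.same_mpg) == same and p.is_ss4r is ss4r]
            if not sel:
                continue
            ident = np.array([p.identity_pct for p in sel])
            shared = np.array([p.shared_pct for p in sel if p.shared_pct is not None])
            rows.append(
                {
                    "stratum": "same_mpg" if same else "different_mpg",
                    "ss4r": {True: "ss4r", False: "other", None: "unknown"}[ss4r],
                    "n_pairs": len(sel),
                    "identity_mean": ident.mean(),
                    "identity_sd": ident.std(ddof=1) if len(ident) > 1 else 0.0,
                    "identity_min": ident.min(),
                    "identity_max": ident.max(),
                    "shared_mean": shared.mean() if shared.size else np.nan,
                    "shared_sd": shared.std(ddof=1) if shared.size > 1 else 0.0,
                    "shared_min": shared.min() if shared.size else np.nan,
                    "shared_max": shared.max() if shared.size else np.nan,
                }
            )
    return pd.DataFrame(rows)
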