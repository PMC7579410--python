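"""Synthetic longitudinal cohort generator.

Emulates the statistical structure of a repeated-measures plasma-proteome
study: a handful of individuals (fish) sampled at fixed days post-
immunization, a few hundred quantified proteins whose variance is dominated
by stable individual differences, a minority of "responder" proteins whose
mean abundance tracks one of five archetypal temporal profiles, paralog pairs
spanning a wide amino-acid-identity range, and sparse low-abundance-biased
(MNAR) missingness.

The log2 abundance model is

    y[p, f, d] = baseline_p + s_p * fish_f + e * a_p(d) * 1{p responder} + eps

with ``fish_f ~ N(0, sigma_individual^2)`` a per-fish intercept shared across
proteins, ``eps ~ N(0, sigma_noise^2)`` residual noise, and ``a_p`` the
protein's archetype profile scaled by the peak amplitude ``e``.  The
individual intercept is attenuated (``s_p < 1``) for responder proteins:
population-level markers are, by definition, the proteins whose within-day
abundances are most consistent across individuals, and an unattenuated
intercept would make day effects of realistic size undetectable by a one-way
analysis that treats fish as replicates.

All randomness is split from one seed by a counter-based scheme, so enlarging
the design never perturbs the draws for existing proteins or fish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rand import child_rng
from .datatypes import CANONICAL_AA, AbundanceTensor, ProteinRecord, SampleKey

__all__ = [
    "ARCHETYPE_NAMES",
    "ARCHETYPES",
    "DEFAULT_DAYS",
    "CohortDesign",
    "TruthTable",
    "simulate_paralog_pair",
    "simulate_proteome",
    "simulate_abundance",
    "apply_missingness",
    "simulate_titres",
    "inject_igm_signal",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: sampling days of the immunization timecourse
DEFAULT_DAYS = (0, 7, 14, 21, 28, 35, 42, 56, 70, 84)

ARCHETYPE_NAMES = ("A1", "A2", "B1", "B2", "B3")

#: Mean-response templates (one value per sampling day, arbitrary log2 units,
#: centred around zero, peak magnitude ~1).  Shapes: A1 late single peak;
#: A2 slow monotone rise; B1 day-7 spike then elevated plateau; B2 mid-course
#: peak with a day-56 trough; B3 early-high profile decaying over the course.
ARCHETYPES = np.array(
    [
        [-0.60, -0.60, -0.60, -0.55, -0.40, -0.10, 0.45, 1.00, 0.70, 0.10],  # A1
        [-1.00, -0.90, -0.75, -0.55, -0.30, 0.00, 0.30, 0.65, 0.90, 1.00],   # A2
        [-1.00, 1.00, 0.50, 0.35, 0.30, 0.30, 0.30, 0.35, 0.50, 0.80],       # B1
        [0.00, -0.15, 0.35, 0.85, 1.00, 0.95, 0.30, -1.00, -0.40, 0.40],     # B2
        [1.00, 0.85, 0.60, 0.35, 0.10, -0.10, -0.30, -0.60, -0.80, -0.90],   # B3
    ]
)


@dataclass
class CohortDesign:
    """Parameters of the simulated study.

    Defaults reproduce the analysed design: 6 individuals x 10 sampling days,
    278 retained proteins, ~15% responders, and a post-filter missingness
    target of 0.78%.  ``sigma_individual`` and ``sigma_noise`` are log2-unit
    SDs; ``effect_size`` is the peak day-effect amplitude in log2 units
    (default 2 x sigma_noise); ``responder_individual_scale`` attenuates the
    per-fish intercept for responder proteins (see module docstring).
    """

    n_individuals: int = 6
    days: tuple[int, ...] = DEFAULT_DAYS
    n_proteins: int = 278
    responder_fraction: float = 0.15
    archetypes: np.ndarray | None = None
    sigma_individual: float = 1.0
    sigma_noise: float = 0.35
    effect_size: float = 0.70
    responder_individual_scale: float = 0.25
    baseline_mean: float = 25.0
    baseline_sd: float = 1.0
    missing_rate: float = 0.0078
    mnar_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must be in [0, 1]")
        if self.sigma_individual < 0 or self.sigma_noise < 0:
            raise ValueError("sigma values must be >= 0")
        if self.n_individuals < 1 or self.n_proteins < 1:
            raise ValueError("n_individuals and n_proteins must be positive")
        arch = ARCHETYPES if self.archetypes is None else np.asarray(self.archetypes, float)
        if arch.shape[1] != len(self.days):
            raise ValueError(
                f"archetypes have {arch.shape[1]} days, design has {len(self.days)}"
            )
        self.archetypes = arch

    @property
    def individuals(self) -> list[str]:
        return [f"F{i + 1}" for i in range(self.n_individuals)]

    @property
    def n_responders(self) -> int:
        return round(self.responder_fraction * self.n_proteins)


@dataclass
class TruthTable:
    """Ground-truth record of a simulated cohort, for parameter-recovery tests."""

    frame: pd.DataFrame  # index protein; columns is_responder, archetype
    profiles: pd.DataFrame  # index protein; columns days; true per-day means

    @property
    def responders(self) -> list[str]:
        return list(self.frame.index[self.frame["is_responder"]])

    def archetype_of(self, protein: str) -> str | None:
        v = self.frame.loc[protein, "archetype"]
        return None if pd.isna(v) else str(v)


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def simulate_paralog_pair(
    template: str,
    target_identity: float,
    seed: int,
    accession_prefix: str = "SIM",
    family: int = 0,
) -> tuple[ProteinRecord, ProteinRecord]:
    """Derive a paralog pair: the template plus a copy carrying uniformly
    placed substitutions so realized identity is within 1 point of target.

    The two records carry distinct gene ids and homeologous chromosome labels
    (``<n>a`` / ``<n>b``), emulating gene duplicates retained from a whole-
    genome duplication.
    """
    template = template.upper()
    if not 50.0 <= target_identity <= 100.0:
        raise ValueError("target_identity must be in [50, 100]")
    if len(template) < 50:
        raise ValueError("template must be at least 50 residues")
    bad = set(template) - CANONICAL_AA
    if bad:
        raise ValueError(f"template contains non-canonical residues {sorted(bad)!r}")

    rng = child_rng(seed, "paralog", family)
    n_sub = int(round(len(template) * (1.0 - target_identity / 100.0)))
    positions = rng.choice(len(template), size=n_sub, replace=False)
    seq_b = list(template)
    for pos in positions:
        alternatives = [a for a in AA_ALPHABET if a != template[pos]]
        seq_b[pos] = alternatives[rng.integers(len(alternatives))]

    chrom = rng.integers(1, 30)
    rec_a = ProteinRecord(
        accession=f"{accession_prefix}{family:04d}a",
        sequence=template,
        gene_id=f"gene{family:04d}a",
        chromosome=f"{chrom}a",
    )
    rec_b = ProteinRecord(
        accession=f"{accession_prefix}{family:04d}b",
        sequence="".join(seq_b),
        gene_id=f"gene{family:04d}b",
        chromosome=f"{chrom}b",
    )
    return rec_a, rec_b


def simulate_proteome(
    n_families: int,
    duplicate_fraction: float,
    identity_range: tuple[float, float] = (70.0, 100.0),
    seed: int = 0,
    length_range: tuple[int, int] = (100, 600),
) -> list[ProteinRecord]:
    """Random protein families; a fixed fraction is expanded into paralog
    pairs at identities drawn uniformly from ``identity_range``."""
    if n_families <= 0:
        raise ValueError("n_families must be positive")
    if not 0.0 <= duplicate_fraction <= 1.0:
        raise ValueError("duplicate_fraction must be in [0, 1]")
    lo, hi = identity_range
    n_dup = round(duplicate_fraction * n_families)
    which_dup = set(
        child_rng(seed, "which_dup").choice(n_families, size=n_dup, replace=False).tolist()
    )
    records: list[ProteinRecord] = []
    for fam in range(n_families):
        rng = child_rng(seed, "family", fam)
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        template = _random_sequence(rng, length)
        if fam in which_dup:
            identity = float(rng.uniform(lo, hi))
            records.extend(simulate_paralog_pair(template, identity, seed, family=fam))
        else:
            records.append(
                ProteinRecord(
                    accession=f"SIM{fam:04d}a",
                    sequence=template,
                    gene_id=f"gene{fam:04d}a",
                    chromosome=str(int(rng.integers(1, 30))),
                )
            )
    return records


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

def simulate_abundance(
    design: CohortDesign, proteins: Sequence[str]
) -> tuple[AbundanceTensor, TruthTable]:
    """Simulate the log2 abundance tensor (fully observed) plus ground truth."""
    proteins = list(proteins)
    if len(proteins) != design.n_proteins:
        raise ValueError(f"expected {design.n_proteins} proteins, got {len(proteins)}")
    days = list(design.days)
    fish_ids = design.individuals
    n_p, n_f, n_d = len(proteins), len(fish_ids), len(days)
    arch = design.archetypes

    seed = design.seed
    fish_effects = np.array(
        [child_rng(seed, "fish", f).normal(0.0, design.sigma_individual) for f in fish_ids]
    )
    n_resp = design.n_responders
    order = child_rng(seed, "responders").permutation(n_p)
    responder_idx = set(order[:n_resp].tolist())

    values = np.empty((n_p, n_f * n_d))
    samples = [SampleKey(f, d) for f in fish_ids for d in days]
    is_resp = np.zeros(n_p, bool)
    arch_label: list[str | None] = []
    profiles = np.empty((n_p, n_d))

    for i, acc in enumerate(proteins):
        rng = child_rng(seed, "protein", acc)
        baseline = rng.normal(design.baseline_mean, design.baseline_sd)
        if i in responder_idx:
            is_resp[i] = True
            a_id = int(rng.integers(len(arch)))
            arch_label.append(ARCHETYPE_NAMES[a_id])
            day_effect = design.effect_size * arch[a_id]
            ind_scale = design.responder_individual_scale
        else:
            arch_label.append(None)
            day_effect = np.zeros(n_d)
            ind_scale = 1.0
        mean_fd = baseline + ind_scale * fish_effects[:, None] + day_effect[None, :]
        eps = rng.normal(0.0, design.sigma_noise, size=(n_f, n_d))
        values[i] = (mean_fd + eps).ravel()
        profiles[i] = baseline + day_effect

    tensor = AbundanceTensor(
        proteins=proteins,
        samples=samples,
        values=values,
        mask=np.ones_like(values, dtype=bool),
        scale="log2",
    )
    truth = TruthTable(
        frame=pd.DataFrame(
            {"is_responder": is_resp, "archetype": arch_label}, index=proteins
        ),
        profiles=pd.DataFrame(profiles, index=proteins, columns=days),
    )
    if design.effect_size == 0.0:
        # zero amplitude: nothing responds, whatever the assignment said
        truth.frame["is_responder"] = False
        truth.frame["archetype"] = None
    return tensor, truth


def apply_missingness(
    tensor: AbundanceTensor,
    missing_rate: float,
    mnar_strength: float = 1.0,
    seed: int = 0,
) -> AbundanceTensor:
    """Mask entries with probability logistic in the (negated) abundance
    z-score, calibrated so the overall masked fraction is ~``missing_rate``.

    ``mnar_strength`` is the logistic slope on the z-score: 0 recovers
    missing-completely-at-random; larger values bias non-detection toward
    low-abundance entries.  Entries already masked stay masked.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    out = tensor.copy()
    if missing_rate == 0.0:
        return out
    obs = out.mask
    vals = out.values[obs]
    z = (out.values - vals.mean()) / (vals.std() or 1.0)

    def masked_fraction(alpha: float) -> float:
        p = 1.0 / (1.0 + np.exp(-(alpha - mnar_strength * z[obs])))
        return float(p.mean())

    lo, hi = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if masked_fraction(mid) < missing_rate:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    prob = 1.0 / (1.0 + np.exp(-(alpha - mnar_strength * z)))
    draws = child_rng(seed, "missing").random(out.values.shape)
    out.mask = obs & ~(draws < prob)
    return out


# ---------------------------------------------------------------------------
# antibody titres
# ---------------------------------------------------------------------------

def simulate_titres(
    design: CohortDesign,
    coupling: float = 0.0,
    seed: int | None = None,
    amplitude: float = 1.0,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Antigen-specific antibody titre curves: a logistic rise with per-fish
    random onset (uniform 21-42 days) and amplitude.

    Returns a tidy table (individual, day, titre) and the noise-free latent
    curves (fish x day); pass the latter to :func:`inject_igm_signal` with the
    same ``coupling`` to drive designated IgM proteins in the tensor.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    if seed is None:
        seed = design.seed
    days = np.asarray(design.days, float)
    fish_ids = design.individuals
    latent = np.empty((len(fish_ids), len(days)))
    rows = []
    for i, f in enumerate(fish_ids):
        rng = child_rng(seed, "titre", f)
        onset = rng.uniform(21.0, 42.0)
        rate = rng.uniform(0.10, 0.25)
        amp = amplitude * rng.uniform(0.6, 1.4)
        curve = amp / (1.0 + np.exp(-rate * (days - onset)))
        latent[i] = curve
        eps = rng.normal(0.0, noise_sd, size=len(days))
        for d, t in zip(design.days, curve + eps):
            rows.append({"individual": f, "day": int(d), "titre": float(t)})
    return pd.DataFrame(rows), latent


def inject_igm_signal(
    tensor: AbundanceTensor,
    latent: np.ndarray,
    igm_accessions: Sequence[str],
    coupling: float,
    scale: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> AbundanceTensor:
    """Add the titre latent curve (times ``coupling * scale``) plus noise to
    the designated IgM protein rows of a log2 tensor."""
    if not igm_accessions:
        raise ValueError("igm_accessions must be non-empty")
    out = tensor.copy()
    fish_ids = out.individuals
    days = out.days
    if latent.shape != (len(fish_ids), len(days)):
        raise ValueError(f"latent shape {latent.shape} != ({len(fish_ids)}, {len(days)})")
    col_of = {(f, d): out.sample_index(f, d) for f in fish_ids for d in days}
    for acc in igm_accessions:
        i = out.protein_index(acc)
        rng = child_rng(seed, "igm", acc)
        for fi, f in enumerate(fish_ids):
            for di, d in enumerate(days):
                j = col_of[(f, d)]
                out.values[i, j] += coupling * scale * latent[fi, di] + rng.normal(0, noise_sd)
    return out
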