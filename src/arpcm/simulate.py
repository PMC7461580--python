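"""Synthetic dose-response curves, mutants, and datasets.

The generator emulates the four curve families seen in reporter assays of AR
mutants treated with anti-androgens:

* antagonist — a sigmoidal Hill decay from 100% toward a low floor,
* mixed-response — the same decay plus a high-dose recovery hump (u-shape),
* agonist — dose-dependent activation above the wild-type level,
* non-responsive — a flat near-zero baseline.

Curves are rejection-sampled against the actual rule classifier so a
requested phenotype is guaranteed to classify as itself — the generator can
never contradict the rule engine.  Datasets pair synthetic mutants with
drugs, optionally coupling phenotype to disjoint mutation sub-regions so the
protein features carry a learnable signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .curves import DEFAULT_GRID, DoseResponseCurve, PhenotypeLabel, RuleThresholds, classify_curve
from .exceptions import SimulationError
from .mutants import AMINO_ACIDS, MutantSpec, Substitution, TrimRegion

#: Default synthetic drug panel: three structurally distinct small molecules
#: (ibuprofen, aspirin, caffeine) standing in for an anti-androgen series so
#: fingerprints differ between drugs without any claim of pharmacology.
DEFAULT_DRUG_SMILES: dict[str, str] = {
    "drug_a": "CC(C)Cc1ccc(cc1)C(C)C(=O)O",
    "drug_b": "CC(=O)Oc1ccccc1C(=O)O",
    "drug_c": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
}

_REJECTION_BUDGET = 100


@dataclass(frozen=True)
class CurveSimConfig:
    """Configuration for one simulated curve."""

    phenotype: PhenotypeLabel
    noise_sd: float = 2.0
    grid: tuple[float, ...] = DEFAULT_GRID
    seed: int = 0
    hard: bool = False  # sample near rule boundaries to stress tie handling

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _curve_values(
    phenotype: PhenotypeLabel, conc: np.ndarray, rng: np.random.Generator, hard: bool
) -> np.ndarray:
    if phenotype is PhenotypeLabel.NON_RESPONSIVE:
        return np.full_like(conc, rng.uniform(0, 4))
    if phenotype is PhenotypeLabel.ANTAGONIST:
        b = rng.uniform(6, 9.5) if hard else rng.uniform(0, 8)
        ic50 = np.exp(rng.uniform(np.log(0.01), np.log(5)))
        h = rng.uniform(0.5, 2)
        return b + (100 - b) / (1 + (conc / ic50) ** h)
    if phenotype is PhenotypeLabel.MIXED_RESPONSE:
        b = rng.uniform(0, 8)
        ic50 = np.exp(rng.uniform(np.log(0.01), np.log(5)))
        h = rng.uniform(0.5, 2)
        base = b + (100 - b) / (1 + (conc / ic50) ** h)
        r = rng.uniform(10.5, 14) if hard else rng.uniform(20, 60)
        K = rng.uniform(1, 20)
        return base + r * conc / (conc + K)
    # agonist
    t = rng.uniform(120, 200)
    E = np.exp(rng.uniform(np.log(0.01), np.log(5)))
    return 100 + (t - 100) * conc / (conc + E)


def simulate_curve(
    config: CurveSimConfig,
    mutant_id: str = "sim_mutant",
    drug_id: str = "sim_drug",
    thresholds: RuleThresholds | None = None,
) -> DoseResponseCurve:
    """Draw one curve of the requested phenotype.

    Parameters are re-drawn (up to 100 tries) until the rule classifier
    applied to the noisy curve returns the requested label, so label
    consistency holds by construction.
    """
    rng = np.random.default_rng(config.seed)
    conc = np.asarray(config.grid, dtype=float)
    for _ in range(_REJECTION_BUDGET):
        values = _curve_values(config.phenotype, conc, rng, config.hard)
        if config.noise_sd > 0:
            values = values + rng.normal(0, config.noise_sd, size=values.shape)
        curve = DoseResponseCurve(mutant_id, drug_id, tuple(conc), tuple(values))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if classify_curve(curve, thresholds) is config.phenotype:
                return curve
    raise SimulationError(
        f"could not generate a {config.phenotype.label} curve in "
        f"{_REJECTION_BUDGET} tries; config is inconsistent with the rules"
    )


def synthetic_wt_sequence(length: int = 200, seed: int = 0) -> str:
    """A synthetic wild-type protein sequence (uniform residues, seeded)."""
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def simulate_mutants(
    wt_sequence: str,
    n: int,
    region: TrimRegion,
    seed: int = 0,
    max_substitutions: int = 2,
) -> list[MutantSpec]:
    """Unique random single/double substitution mutants within a region."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if region.end > len(wt_sequence):
        raise ValueError(
            f"region [{region.start}, {region.end}] exceeds sequence length {len(wt_sequence)}"
        )
    rng = np.random.default_rng(seed)
    positions = np.arange(region.start, region.end + 1)
    if n > len(positions) * 19:
        raise ValueError(f"cannot draw {n} unique mutants from region {region}")
    specs: dict[str, MutantSpec] = {}
    guard = 0
    while len(specs) < n:
        guard += 1
        if guard > 100 * n + 1000:
            raise SimulationError("mutant sampling stalled; region too small")
        n_subs = int(rng.integers(1, max_substitutions + 1))
        pos = rng.choice(positions, size=min(n_subs, len(positions)), replace=False)
        subs = []
        for p in sorted(int(v) for v in pos):
            wt = wt_sequence[p - 1]
            alternatives = [aa for aa in AMINO_ACIDS if aa != wt]
            subs.append(Substitution(wt, p, str(rng.choice(alternatives))))
        spec = MutantSpec("+".join(map(str, subs)), tuple(subs))
        specs.setdefault(spec.mutant_id, spec)
    return list(specs.values())[:n]


@dataclass
class SimulatedDataset:
    """Everything one pipeline run needs, in memory."""

    wt_sequence: str
    curves: list[DoseResponseCurve]
    specs: list[MutantSpec]
    smiles_by_drug: dict[str, str]
    truth: list[tuple[str, str, PhenotypeLabel]]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        return [(m, d) for m, d, _ in self.truth]

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([int(lab) for _, _, lab in self.truth])


def simulate_dataset(
    n_per_class: int | Mapping[PhenotypeLabel, int] = 10,
    drugs: Mapping[str, str] | None = None,
    wt_sequence: str | None = None,
    seed: int = 0,
    noise_sd: float = 2.0,
    couple_features: bool = True,
    region: TrimRegion | None = None,
    hard: bool = False,
) -> SimulatedDataset:
    """Simulate a labelled mutant-drug dataset.

    ``n_per_class`` is either one count for all four classes or a mapping for
    an imbalanced profile.  Each synthetic mutant carries one phenotype; all
    of its drug pairings get curves of that phenotype.  With
    ``couple_features`` (default) the four phenotypes draw their substitution
    positions from four disjoint quarters of the region, so the z-scale block
    carries a signal the models can learn.
    """
    rng = np.random.default_rng(seed)
    drugs = dict(drugs or DEFAULT_DRUG_SMILES)
    wt = wt_sequence or synthetic_wt_sequence(seed=seed)
    region = region or TrimRegion(1, len(wt))
    if isinstance(n_per_class, Mapping):
        profile = {PhenotypeLabel(k): int(v) for k, v in n_per_class.items()}
    else:
        profile = {lab: int(n_per_class) for lab in PhenotypeLabel}
    if any(v < 1 for v in profile.values()):
        raise ValueError("every requested class count must be >= 1")

    # disjoint sub-regions per phenotype when coupling is on
    subregions: dict[PhenotypeLabel, TrimRegion] = {}
    quarter = region.length // 4
    if couple_features and quarter >= 2:
        for i, lab in enumerate(PhenotypeLabel):
            start = region.start + i * quarter
            end = region.start + (i + 1) * quarter - 1 if i < 3 else region.end
            subregions[lab] = TrimRegion(start, end)
    else:
        subregions = {lab: region for lab in PhenotypeLabel}

    drug_ids = sorted(drugs)
    curves: list[DoseResponseCurve] = []
    truth: list[tuple[str, str, PhenotypeLabel]] = []
    specs: list[MutantSpec] = []
    seen_ids: set[str] = set()
    for lab in PhenotypeLabel:
        n_curves = profile[lab]
        n_mut = int(np.ceil(n_curves / len(drug_ids)))
        mut_seed = int(rng.integers(2**31))
        cand = simulate_mutants(wt, n_mut + 5, subregions[lab], seed=mut_seed)
        cand = [s for s in cand if s.mutant_id not in seen_ids][:n_mut]
        if len(cand) < n_mut:
            raise SimulationError("could not draw enough unique mutants")
        seen_ids.update(s.mutant_id for s in cand)
        specs.extend(cand)
        made = 0
        for mi in range(n_mut):
            for d in drug_ids:
                if made >= n_curves:
                    break
                cfg = CurveSimConfig(
                    phenotype=lab,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(2**31)),
                    hard=hard,
                )
                curves.append(simulate_curve(cfg, cand[mi].mutant_id, d))
                truth.append((cand[mi].mutant_id, d, lab))
                made += 1
    return SimulatedDataset(
        wt_sequence=wt, curves=curves, specs=specs, smiles_by_drug=drugs, truth=truth
    )
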