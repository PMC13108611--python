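"""Synthetic longitudinal cohort with planted enterosignature structure.

The generator emulates the study design this package targets: two
divergently selected genetic lines of lactating sows (heat-tolerant TOL,
n = 13; heat-sensitive SEN, n = 12) sampled on days 4, 8 and 14 of
lactation, with one sample dropped at random (75 -> 74 usable samples).
Each sample's community is a mixed membership over ``k_true`` latent
subcommunities: loadings ``W_true`` are Dirichlet-distributed on the
simplex with optional additive (line, timepoint)-specific shifts, and
signature profiles ``H_true`` are sparse non-negative rows over
features.  Counts are multinomial (optionally Dirichlet-multinomial
overdispersed) draws from the composite proportions ``W_true @ H_true``,
and phenotypes are linear in the true loadings plus design offsets and
Gaussian noise — so recovery of rank, factors, effects and regression
coefficients can all be scored against known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import AbundanceMatrix

TIMEPOINTS = ("d4", "d8", "d14")
LINES = ("TOL", "SEN")

# EffectSpec: {(line, timepoint): {signature_index: additive shift}}
EffectSpec = dict[tuple[str, str], dict[int, float]]


@dataclass
class GroundTruth:
    """Planted latent structure behind a synthetic cohort.

    ``W_true`` rows and ``H_true`` rows each sum to 1; ``effect_spec``
    holds the additive loading shifts per (line, timepoint); and
    ``pheno_beta`` maps phenotype name -> per-signature regression
    coefficients.
    """

    W_true: np.ndarray
    H_true: np.ndarray
    k_true: int
    effect_spec: EffectSpec = field(default_factory=dict)
    pheno_beta: dict[str, np.ndarray] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.W_true = np.asarray(self.W_true, dtype=float)
        self.H_true = np.asarray(self.H_true, dtype=float)
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        if (self.W_true < 0).any() or (self.H_true < 0).any():
            raise ValueError("ground-truth factors must be non-negative")
        for name, mat in (("W_true", self.W_true), ("H_true", self.H_true)):
            sums = mat.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"rows of {name} must sum to 1")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "W_true": self.W_true.tolist(),
            "H_true": self.H_true.tolist(),
            "k_true": self.k_true,
            "effect_spec": [
                {"line": ln, "timepoint": tp, "shifts": {str(k): v for k, v in d.items()}}
                for (ln, tp), d in self.effect_spec.items()
            ],
            "pheno_beta": {p: b.tolist() for p, b in self.pheno_beta.items()},
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))


def make_metadata(
    n_tol: int = 13,
    n_sen: int = 12,
    timepoints: tuple[str, ...] = TIMEPOINTS,
    drop: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Build the longitudinal sample sheet: one row per (animal, timepoint),
    with ``drop`` rows removed uniformly at random (mirroring samples lost
    to sequencing quality).

    Returns a DataFrame with columns sample_id, animal_id, line, timepoint.
    """
    if n_tol < 1 or n_sen < 1:
        raise ValueError("each line needs at least one animal")
    n_animals = n_tol + n_sen
    if drop < 0 or drop >= n_animals * len(timepoints):
        raise ValueError("drop must be in [0, n_animals * n_timepoints)")
    rows = []
    for a in range(n_animals):
        line = "TOL" if a < n_tol else "SEN"
        animal = f"{line}{a + 1:02d}" if a < n_tol else f"{line}{a - n_tol + 1:02d}"
        for tp in timepoints:
            rows.append(
                {
                    "sample_id": f"{animal}_{tp}",
                    "animal_id": animal,
                    "line": line,
                    "timepoint": tp,
                }
            )
    df = pd.DataFrame(rows)
    if drop:
        rng = np.random.default_rng(seed)
        dropped = rng.choice(len(df), size=drop, replace=False)
        df = df.drop(index=dropped).reset_index(drop=True)
    return df


def plant_signatures(
    metadata: pd.DataFrame,
    k_true: int = 4,
    n_features: int = 300,
    alpha: float = 0.3,
    h_sparsity: float = 0.8,
    effect_spec: EffectSpec | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw mixed-membership loadings and sparse signature profiles.

    ``W_true`` rows come from a symmetric Dirichlet(``alpha``); small
    ``alpha`` gives spiky memberships (one dominant subcommunity per
    sample), large ``alpha`` approaches uniform membership.  Effects in
    ``effect_spec`` are added to the named signature's loading for all
    samples in that (line, timepoint) cell, then rows are clipped at
    zero and renormalized so they stay on the simplex.  ``H_true`` rows
    are exponential variates with an expected ``h_sparsity`` fraction
    zeroed (each signature keeps at least one feature), renormalized.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not (0 <= h_sparsity < 1):
        raise ValueError("h_sparsity must be in [0, 1)")
    effect_spec = effect_spec or {}
    for (ln, tp), shifts in effect_spec.items():
        for j in shifts:
            if not (0 <= j < k_true):
                raise ValueError(f"effect_spec references unknown signature {j}")
    rng = np.random.default_rng(seed)
    n = len(metadata)
    W = rng.dirichlet(np.full(k_true, alpha), size=n)
    for i, row in enumerate(metadata.itertuples(index=False)):
        shifts = effect_spec.get((row.line, row.timepoint))
        if shifts:
            for j, delta in shifts.items():
                W[i, j] += delta
    W = np.clip(W, 0.0, None)
    W /= W.sum(axis=1, keepdims=True)

    H = rng.exponential(1.0, size=(k_true, n_features))
    mask = rng.random((k_true, n_features)) < h_sparsity
    H[mask] = 0.0
    for s in range(k_true):
        if H[s].sum() == 0:  # a signature must load on something
            H[s, rng.integers(n_features)] = 1.0
    H /= H.sum(axis=1, keepdims=True)

    return GroundTruth(
        W_true=W, H_true=H, k_true=k_true, effect_spec=effect_spec, seed=seed
    )


def sample_counts(
    ground_truth: GroundTruth,
    metadata: pd.DataFrame,
    depth: int = 100_000,
    overdispersion: float = 0.0,
    seed: int = 0,
    kind: str = "MAG",
) -> AbundanceMatrix:
    """Draw per-sample count vectors from the composite proportions.

    With ``overdispersion`` = 0 each sample is multinomial(depth, p) with
    p the sample's row of ``W_true @ H_true``; otherwise p is first
    perturbed by a Dirichlet draw with concentration p / overdispersion
    (larger values -> more extra-multinomial variance), the standard
    Dirichlet-multinomial noise model for metagenomic counts.  Every row
    sums exactly to ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if overdispersion < 0:
        raise ValueError("overdispersion must be >= 0")
    P = ground_truth.W_true @ ground_truth.H_true
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("rows of W_true @ H_true must sum to 1")
    rng = np.random.default_rng(seed)
    counts = np.empty_like(P, dtype=float)
    for i in range(P.shape[0]):
        p = P[i] / P[i].sum()
        if overdispersion > 0:
            conc = np.maximum(p / overdispersion, 1e-12)
            p = rng.dirichlet(conc)
        counts[i] = rng.multinomial(depth, p)
    feature_prefix = "MAG" if kind == "MAG" else "KO"
    return AbundanceMatrix(
        values=counts,
        sample_ids=list(metadata["sample_id"]),
        feature_ids=[f"{feature_prefix}{j:04d}" for j in range(P.shape[1])],
        kind=kind,
    )


def make_ko_map(
    mag_ids: list[str],
    n_kos: int = 6000,
    n_guilds: int = 8,
    kos_per_mag: int = 120,
    shared_fraction: float = 0.6,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Assign each MAG a KO repertoire with guild-block redundancy.

    MAGs are partitioned into ``n_guilds`` functional guilds; members of
    a guild share a common KO block (``shared_fraction`` of their
    repertoire) and draw the remainder privately, emulating the
    functional redundancy seen when distinct taxa carry similar
    metabolic repertoires.
    """
    if not mag_ids:
        raise ValueError("mag_ids must be non-empty")
    rng = np.random.default_rng(seed)
    kos = np.array([f"K{j:05d}" for j in range(n_kos)])
    guild_of = rng.integers(n_guilds, size=len(mag_ids))
    n_shared = int(round(kos_per_mag * shared_fraction))
    guild_blocks = [
        set(rng.choice(kos, size=n_shared, replace=False)) for _ in range(n_guilds)
    ]
    mapping: dict[str, set[str]] = {}
    for mag, g in zip(mag_ids, guild_of):
        private = set(rng.choice(kos, size=kos_per_mag - n_shared, replace=False))
        mapping[mag] = guild_blocks[g] | private
    return mapping


def derive_ko_matrix(
    mag_matrix: AbundanceMatrix, mag_ko_map: dict[str, set[str]]
) -> AbundanceMatrix:
    """Aggregate MAG abundances into a sample x KO matrix.

    KO abundance(sample, ko) = sum of abundances of the MAGs carrying
    that KO; columns are the sorted union of mapped KOs.
    """
    if not mag_ko_map:
        raise ValueError("MAG -> KO map is empty")
    missing = [m for m in mag_matrix.feature_ids if m not in mag_ko_map]
    if missing:
        raise ValueError(f"MAGs absent from the KO map: {missing[:5]}")
    all_kos = sorted(set().union(*mag_ko_map.values()))
    ko_index = {k: j for j, k in enumerate(all_kos)}
    # indicator: MAGs x KOs
    A = np.zeros((mag_matrix.n_features, len(all_kos)))
    for i, mag in enumerate(mag_matrix.feature_ids):
        for ko in mag_ko_map[mag]:
            A[i, ko_index[ko]] = 1.0
    return AbundanceMatrix(
        values=mag_matrix.values @ A,
        sample_ids=list(mag_matrix.sample_ids),
        feature_ids=all_kos,
        kind="KO",
    )


DEFAULT_PHENOTYPES = (
    "respiration_rate",
    "vaginal_temperature",
    "feed_intake",
    "cortisol",
)


def generate_phenotypes(
    ground_truth: GroundTruth,
    metadata: pd.DataFrame,
    noise_sd: float = 0.5,
    pheno_beta: dict[str, np.ndarray] | None = None,
    line_offsets: dict[str, dict[str, float]] | None = None,
    time_offsets: dict[str, dict[str, float]] | None = None,
    intercepts: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Phenotypes linear in the true loadings.

    P = mu_p + sum_j beta_pj * W_true[:, j] + line/time offsets +
    N(0, noise_sd).  When ``pheno_beta`` is omitted, one unit-coefficient
    phenotype per signature is generated (plus defaults stored on the
    ground truth if present).
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    k = ground_truth.k_true
    if pheno_beta is None:
        pheno_beta = ground_truth.pheno_beta or {
            name: np.eye(k)[i % k] * 2.0
            for i, name in enumerate(DEFAULT_PHENOTYPES)
        }
    for name, beta in pheno_beta.items():
        if len(np.atleast_1d(beta)) != k:
            raise ValueError(f"pheno_beta[{name!r}] must have length k_true={k}")
    ground_truth.pheno_beta = {p: np.atleast_1d(np.asarray(b, float)) for p, b in pheno_beta.items()}
    line_offsets = line_offsets or {}
    time_offsets = time_offsets or {}
    intercepts = intercepts or {}
    rng = np.random.default_rng(seed)
    out = metadata[["sample_id"]].copy()
    for name, beta in ground_truth.pheno_beta.items():
        base = float(intercepts.get(name, 0.0)) + ground_truth.W_true @ beta
        lo = line_offsets.get(name, {})
        to = time_offsets.get(name, {})
        base = base + metadata["line"].map(lambda x: lo.get(x, 0.0)).to_numpy()
        base = base + metadata["timepoint"].map(lambda x: to.get(x, 0.0)).to_numpy()
        out[name] = base + rng.normal(0.0, noise_sd, size=len(metadata))
    return out


@dataclass
class SyntheticCohort:
    """Bundle of everything one simulation produces."""

    metadata: pd.DataFrame
    truth: GroundTruth
    mag_matrix: AbundanceMatrix
    ko_matrix: AbundanceMatrix | None
    phenotypes: pd.DataFrame


def simulate_cohort(
    k_true: int = 4,
    n_features: int = 300,
    n_tol: int = 13,
    n_sen: int = 12,
    timepoints: tuple[str, ...] = TIMEPOINTS,
    drop: int = 1,
    alpha: float = 0.3,
    h_sparsity: float = 0.8,
    depth: int = 100_000,
    overdispersion: float = 0.0,
    effect_spec: EffectSpec | None = None,
    noise_sd: float = 0.5,
    with_ko: bool = False,
    seed: int = 0,
) -> SyntheticCohort:
    """One-call cohort simulation wiring the stages together.

    Derived seeds are offsets of ``seed`` so each stage has an
    independent stream but the whole cohort is reproducible from one
    integer.
    """
    metadata = make_metadata(n_tol, n_sen, timepoints, drop=drop, seed=seed)
    truth = plant_signatures(
        metadata, k_true, n_features, alpha=alpha, h_sparsity=h_sparsity,
        effect_spec=effect_spec, seed=seed + 1,
    )
    mag = sample_counts(
        truth, metadata, depth=depth, overdispersion=overdispersion, seed=seed + 2
    )
    ko = None
    if with_ko:
        ko_map = make_ko_map(mag.feature_ids, seed=seed + 3)
        ko = derive_ko_matrix(mag, ko_map)
    phenos = generate_phenotypes(truth, metadata, noise_sd=noise_sd, seed=seed + 4)
    return SyntheticCohort(metadata, truth, mag, ko, phenos)
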