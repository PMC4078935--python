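"""Synthetic data with the statistical structure of a mule-duck study.

Generates, from one seeded configuration:

* a pedigree per parental line (common dam line, Muscovy sire line),
* line-specific transmitted genetic effects sampled under the additive
  infinitesimal model (covariance A (x) G per line),
* crossbred fatty-liver phenotypes under the sire-dam model
  y = fixed level + dam-line effect + sire-line effect + residual,
* liver composition (dry matter, ash, lipid, protein, melting rate) and
* raw reflectance-style absorbance spectra whose signal is linear in
  composition plus baseline, scatter and noise artifacts.

The defaults emulate the study population: 1422 crossbreds from 382 dams
and 56 sires, pedigrees of 596 (common) and 201 (Muscovy) animals traced
over five generations, 12 fixed-effect levels (year x batch x force-feeder),
and a melting rate with mean 35.6% and SD 14.7%. Generating variance
fractions default to dam-line 0.20 and sire-line 0.10 of the total.

Transmitted effects are simulated directly as the parent's line-specific
effect as expressed in the crossbred phenotype (one effect per parent,
variance equal to the line component); the crossbred's own Mendelian
sampling is folded into the residual, exactly as the fitted model assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import pedigree as pg
from .pedigree import UNKNOWN, Pedigree
from .spectra import SpectraSet

# melting-rate phenotypic variance split: 14.7^2 total, fractions 0.20 dam /
# 0.10 sire / 0.70 residual
_MR_VAR = 14.7**2

#: synthetic near-infrared band library: constituent -> (center nm, width nm,
#: intensity per unit mass fraction). Moisture is 100 - dry matter.
DEFAULT_BAND_LIBRARY: dict = {
    "moisture": [(970, 40, 0.6), (1190, 45, 0.5), (1450, 50, 1.2), (1940, 55, 1.5)],
    "Lip": [(1210, 30, 0.9), (1390, 35, 0.5), (1725, 30, 1.1), (2310, 35, 1.0), (2350, 35, 0.8)],
    "Prot": [(1510, 40, 0.6), (2055, 40, 0.8), (2180, 40, 0.7)],
    "AC": [(2200, 80, 0.2)],
    "MR": [(1760, 25, 0.05), (2280, 30, 0.04)],
}


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic population."""

    n_crossbreds: int = 1422
    n_dams: int = 382
    n_sires: int = 56
    common_pedigree_size: int = 596
    muscovy_pedigree_size: int = 201
    pedigree_generations: int = 5
    n_fixed_levels: int = 12
    trait_names: tuple = ("mMR",)
    trait_means: tuple = (35.6,)
    G_dam: np.ndarray = field(default_factory=lambda: np.array([[0.20 * _MR_VAR]]))
    G_sire: np.ndarray = field(default_factory=lambda: np.array([[0.10 * _MR_VAR]]))
    R: np.ndarray = field(default_factory=lambda: np.array([[0.70 * _MR_VAR]]))
    fixed_effect_sd: float = 2.0
    spectral_grid: np.ndarray = field(
        default_factory=lambda: np.arange(350.0, 2502.0, 2.0)
    )
    band_library: dict = field(default_factory=lambda: dict(DEFAULT_BAND_LIBRARY))
    baseline_sd: float = 0.05
    scatter_mult_sd: float = 0.05
    scatter_offset_sd: float = 0.02
    noise_sd: float = 0.025
    replicates_surface: int = 6
    replicates_ground: int = 3
    seed: int = 0

    def __post_init__(self):
        self.G_dam = np.atleast_2d(np.asarray(self.G_dam, dtype=float))
        self.G_sire = np.atleast_2d(np.asarray(self.G_sire, dtype=float))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=float))
        t = len(self.trait_names)
        for name, M in (("G_dam", self.G_dam), ("G_sire", self.G_sire), ("R", self.R)):
            if M.shape != (t, t):
                raise ValueError(f"{name} must be {t}x{t} for {t} traits")
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-8 * max(1.0, np.abs(M).max()):
                raise ValueError(f"{name} must be positive semi-definite")
        for count in (
            self.n_crossbreds, self.n_dams, self.n_sires, self.n_fixed_levels,
            self.common_pedigree_size, self.muscovy_pedigree_size,
            self.pedigree_generations,
        ):
            if count < 1:
                raise ValueError("all design counts must be positive")
        if np.any(np.diff(self.spectral_grid) <= 0):
            raise ValueError("spectral grid must be strictly increasing")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


def bivariate_config(
    r_dam: float,
    r_sire: float,
    h2_dam=(0.20, 0.20),
    h2_sire=(0.10, 0.12),
    r_resid: float = 0.9,
    trait_names=("traitA", "traitB"),
    total_var: float = _MR_VAR,
    **overrides,
) -> SimulationConfig:
    """Two-trait configuration from heritabilities and genetic correlations.

    ``r_resid`` is an assumption: two measurements of nearly the same trait
    on the same liver share most of their residual (Mendelian sampling plus
    the liver itself). The default 0.9 is what a phenotypic correlation of
    about 0.93 between measured and NIRS-predicted melting rate implies
    once the genetic covariances (h2 of 0.2 dam / 0.1 sire, genetic
    correlation about 0.9) are accounted for.
    """

    def cov(fracs, r):
        v = np.array(fracs) * total_var
        sd = np.sqrt(v)
        return np.array([[v[0], r * sd[0] * sd[1]], [r * sd[0] * sd[1], v[1]]])

    e_frac = 1.0 - np.array(h2_dam) - np.array(h2_sire)
    if np.any(e_frac <= 0):
        raise ValueError("heritabilities leave no residual variance")
    return SimulationConfig(
        trait_names=tuple(trait_names),
        trait_means=(35.6, 35.6),
        G_dam=cov(h2_dam, r_dam),
        G_sire=cov(h2_sire, r_sire),
        R=cov(e_frac, r_resid),
        **overrides,
    )


# ---------------------------------------------------------------------------
# pedigree simulation


@dataclass
class SimulatedPedigrees:
    common: Pedigree
    muscovy: Pedigree
    dam_ids: np.ndarray  # crossbred dams, ids within the common pedigree
    sire_ids: np.ndarray  # crossbred sires, ids within the Muscovy pedigree


def _generation_sizes(total: int, final: int, generations: int) -> list[int]:
    ancestors = total - final
    if ancestors < 0:
        raise ValueError(
            f"pedigree of {total} cannot contain {final} final-generation parents"
        )
    if generations == 1:
        if ancestors:
            raise ValueError("one generation requested but ancestors remain")
        return [final]
    n_anc_gens = generations - 1
    if ancestors < 2 * n_anc_gens:
        raise ValueError(
            f"{ancestors} ancestors cannot fill {n_anc_gens} generations (>= 2 each)"
        )
    base = ancestors // n_anc_gens
    sizes = [base + (1 if g < ancestors % n_anc_gens else 0) for g in range(n_anc_gens)]
    return sizes + [final]


def _simulate_line(total, final, generations, rng, line) -> Pedigree:
    sizes = _generation_sizes(total, final, generations)
    ids = np.arange(1, total + 1)
    sire = np.full(total, UNKNOWN, dtype=np.int64)
    dam = np.full(total, UNKNOWN, dtype=np.int64)
    start = 0
    prev = None
    for size in sizes:
        members = np.arange(start, start + size)
        if prev is not None:
            for m in members:
                s, d = rng.choice(prev, size=2, replace=False)
                sire[m], dam[m] = s, d
        start += size
        prev = members
    return Pedigree(ids=ids, sire=sire, dam=dam, line=line)


def simulate_pedigree(config: SimulationConfig, rng=None) -> SimulatedPedigrees:
    """Simulate both parental-line pedigrees.

    The crossbred dams (sires) are the final generation of the common
    (Muscovy) pedigree; earlier generations hold their ancestors, split as
    evenly as possible across the requested depth.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    common = _simulate_line(
        config.common_pedigree_size, config.n_dams, config.pedigree_generations,
        rng, "common",
    )
    muscovy = _simulate_line(
        config.muscovy_pedigree_size, config.n_sires, config.pedigree_generations,
        rng, "muscovy",
    )
    return SimulatedPedigrees(
        common=common,
        muscovy=muscovy,
        dam_ids=common.ids[-config.n_dams:],
        sire_ids=muscovy.ids[-config.n_sires:],
    )


# ---------------------------------------------------------------------------
# genetic effects and phenotypes


def _chol_psd(M: np.ndarray) -> np.ndarray:
    """Square root of a PSD matrix (eigen-based, tolerant of zero modes)."""
    w, V = np.linalg.eigh(np.atleast_2d(M))
    if w.min() < -1e-8 * max(1.0, np.abs(w).max()):
        raise ValueError("covariance matrix is not positive semi-definite")
    return V * np.sqrt(np.clip(w, 0, None))


def simulate_breeding_values(ped: Pedigree, G: np.ndarray, rng) -> np.ndarray:
    """Sample per-animal genetic effects with covariance A (x) G.

    Founders are independent N(0, G); a non-founder is the mean of its
    parents' values plus a Mendelian deviation whose variance follows the
    pedigree rules (accounting for parental inbreeding).
    """
    G = np.atleast_2d(np.asarray(G, dtype=float))
    t = G.shape[0]
    L = _chol_psd(G)
    f = pg.inbreeding(ped)
    u = np.zeros((len(ped), t))
    z = rng.standard_normal((len(ped), t))
    for i in range(len(ped)):
        s, d = ped.sire[i], ped.dam[i]
        mean = np.zeros(t)
        if s != UNKNOWN:
            mean += 0.5 * u[s]
        if d != UNKNOWN:
            mean += 0.5 * u[d]
        scale = np.sqrt(pg._mendelian_variance(ped, f, i))
        u[i] = mean + scale * (L @ z[i])
    return u


def simulate_crossbreds(
    peds: SimulatedPedigrees,
    bv_dam: np.ndarray,
    bv_sire: np.ndarray,
    config: SimulationConfig,
    rng,
):
    """Crossbred phenotypes under the sire-dam model.

    Each dam is mated to a single sire (crossbreds are full sibs within dam
    and a mix of full and half sibs within sire); fixed-effect levels rotate
    over the birth order so each family spans several levels. Returns
    ``(dataset, truth)`` DataFrames; truth carries every generated effect.
    """
    t = config.n_traits
    n = config.n_crossbreds
    dam_pos = np.array([peds.common.position(a) for a in peds.dam_ids])
    sire_pos = np.array([peds.muscovy.position(a) for a in peds.sire_ids])
    # dam -> sire assignment (round robin), then crossbreds spread over dams
    dam_of = np.arange(n) % config.n_dams
    sire_of_dam = np.arange(config.n_dams) % config.n_sires
    sire_of = sire_of_dam[dam_of]
    level = np.arange(n) % config.n_fixed_levels
    level_effects = rng.normal(0.0, config.fixed_effect_sd, size=(config.n_fixed_levels, t))
    resid = rng.standard_normal((n, t)) @ _chol_psd(config.R).T
    u_dam = bv_dam[dam_pos[dam_of]]
    u_sire = bv_sire[sire_pos[sire_of]]
    means = np.asarray(config.trait_means, dtype=float)
    y = means + level_effects[level] + u_dam + u_sire + resid
    animal = np.array([f"C{i + 1:05d}" for i in range(n)])
    dataset = pd.DataFrame(
        {
            "animal": animal,
            "dam": peds.dam_ids[dam_of],
            "sire": peds.sire_ids[sire_of],
            "fixed_level": level + 1,
        }
    )
    truth = dataset.copy()
    for j, name in enumerate(config.trait_names):
        dataset[name] = y[:, j]
        truth[f"fixed_{name}"] = level_effects[level, j]
        truth[f"dam_effect_{name}"] = u_dam[:, j]
        truth[f"sire_effect_{name}"] = u_sire[:, j]
        truth[f"residual_{name}"] = resid[:, j]
    return dataset, truth


def derive_composition(mr: np.ndarray, rng) -> pd.DataFrame:
    """Liver composition (% units) consistent with a given melting rate.

    Fattier livers melt more: lipid and dry matter increase with the melting
    rate, protein decreases, ash is nearly constant. Slopes and noise levels
    are assumptions of the generator (typical of overfed duck fatty liver),
    not estimates from data.
    """
    mr = np.asarray(mr, dtype=float)
    d = mr - 35.6
    comp = pd.DataFrame(
        {
            "DM": 62.0 + 0.30 * d + rng.normal(0, 3.0, len(mr)),
            "AC": 0.55 + rng.normal(0, 0.05, len(mr)),
            "Lip": 55.0 + 0.40 * d + rng.normal(0, 4.5, len(mr)),
            "Prot": 9.0 - 0.10 * d + rng.normal(0, 1.2, len(mr)),
            "MR": mr,
        }
    )
    return comp.clip(lower=0.01)


def simulate_spectra(
    composition: pd.DataFrame,
    config: SimulationConfig,
    rng,
    mode: str = "ground",
    sample_ids=None,
) -> SpectraSet:
    """Forward NIRS model: absorbance linear in composition plus artifacts.

    Per replicate r of sample i:
        A_ir = m_ir * (signal_i + baseline_i) + o_ir + noise
    where signal_i = sum_k (c_ik / 100) * band profile_k, the baseline is a
    random per-sample quadratic in wavelength, m_ir is multiplicative
    scatter with mean 1 and o_ir an additive offset. 'ground' mode uses 3
    replicates per sample, 'surface' 6.
    """
    grid = config.spectral_grid
    comp_cols = [c for c in composition.columns if c in config.band_library or c == "DM"]
    vals = composition[comp_cols].to_numpy(float)
    if np.any(vals < 0):
        raise ValueError("negative composition values")
    n = len(composition)
    n_rep = config.replicates_ground if mode == "ground" else config.replicates_surface

    profiles = {}
    for name, bands in config.band_library.items():
        p = np.zeros_like(grid)
        for center, width, intensity in bands:
            p += intensity * np.exp(-0.5 * ((grid - center) / width) ** 2)
        profiles[name] = p

    signal = np.zeros((n, len(grid)))
    for col in comp_cols:
        if col == "DM":
            signal += ((100.0 - composition["DM"].to_numpy()) / 100.0)[:, None] * profiles[
                "moisture"
            ]
        else:
            signal += (composition[col].to_numpy() / 100.0)[:, None] * profiles[col]

    x = (grid - grid.mean()) / (grid[-1] - grid[0])
    base_coef = rng.normal(0, config.baseline_sd, size=(n, 3))
    baseline = base_coef[:, [0]] + base_coef[:, [1]] * x + base_coef[:, [2]] * x**2

    if sample_ids is None:
        sample_ids = np.array([f"S{i + 1:05d}" for i in range(n)])
    rows, sids, rids = [], [], []
    clean = signal + baseline
    for r in range(n_rep):
        m = 1.0 + rng.normal(0, config.scatter_mult_sd, size=(n, 1))
        o = rng.normal(0, config.scatter_offset_sd, size=(n, 1))
        eps = rng.normal(0, config.noise_sd, size=(n, len(grid)))
        rows.append(m * clean + o + eps)
        sids.append(np.asarray(sample_ids))
        rids.append(np.full(n, r + 1))
    order = np.argsort(np.concatenate([np.arange(n)] * n_rep), kind="stable")
    values = np.vstack(rows)[order]
    return SpectraSet(
        wavelengths=grid,
        values=values,
        sample_ids=np.concatenate(sids)[order],
        replicate_ids=np.concatenate(rids)[order],
        instrument="ground" if mode == "ground" else "surface",
    )


def simulate_liver_weights(composition: pd.DataFrame, rng) -> np.ndarray:
    """Liver weight (g) loosely increasing with lipid content; used by the
    optional commercial-range truncation filter."""
    lip = composition["Lip"].to_numpy()
    return 550.0 + 6.0 * (lip - 55.0) + rng.normal(0, 80.0, len(lip))


def filter_by_weight(dataset: pd.DataFrame, weights, lo=300.0, hi=830.0):
    """Keep records whose liver weight falls in the commercial range."""
    keep = (np.asarray(weights) >= lo) & (np.asarray(weights) <= hi)
    return dataset.loc[keep].reset_index(drop=True), keep


# ---------------------------------------------------------------------------
# one-call generator


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    pedigrees: SimulatedPedigrees
    dataset: pd.DataFrame
    truth: pd.DataFrame
    composition: pd.DataFrame | None = None
    spectra_ground: SpectraSet | None = None
    spectra_surface: SpectraSet | None = None

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.pedigrees.common.write_csv(out / "pedigree_common.csv")
        self.pedigrees.muscovy.write_csv(out / "pedigree_muscovy.csv")
        self.dataset.to_csv(out / "phenotypes.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        if self.composition is not None:
            self.composition.to_csv(out / "composition.csv", index=False)
        if self.spectra_ground is not None:
            self.spectra_ground.write_csv(out / "spectra_ground.csv")
        if self.spectra_surface is not None:
            self.spectra_surface.write_csv(out / "spectra_surface.csv")


def simulate_study(config: SimulationConfig, spectra: bool = False) -> SimulatedStudy:
    """Run the full generator: pedigrees, genetic effects, phenotypes and
    (optionally) composition plus raw spectra for both measurement modes."""
    rng = np.random.default_rng(config.seed)
    peds = simulate_pedigree(config, rng)
    bv_dam = simulate_breeding_values(peds.common, config.G_dam, rng)
    bv_sire = simulate_breeding_values(peds.muscovy, config.G_sire, rng)
    dataset, truth = simulate_crossbreds(peds, bv_dam, bv_sire, config, rng)
    study = SimulatedStudy(config, peds, dataset, truth)
    if spectra:
        mr = dataset[config.trait_names[0]].to_numpy()
        comp = derive_composition(mr, rng)
        comp.insert(0, "animal", dataset["animal"])
        study.composition = comp
        study.spectra_ground = simulate_spectra(
            comp, config, rng, mode="ground", sample_ids=dataset["animal"].to_numpy()
        )
        study.spectra_surface = simulate_spectra(
            comp, config, rng, mode="surface", sample_ids=dataset["animal"].to_numpy()
        )
    return study
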