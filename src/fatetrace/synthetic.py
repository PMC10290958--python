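"""Synthetic data generators with planted ground truth.

Three generators back the test surface of the whole pipeline:

* :func:`simulate_bifurcation` — negative-binomial UMI counts for a
  progenitor (P) population that splits into two fates (U, L), with
  branch-specific genes whose expression departs from a shared baseline
  at planted divergence times and with planted kinetic archetypes.
* :func:`simulate_mixture` — two-component signature mixtures for the
  deconvolution stage.
* :func:`simulate_dot_image` — bright non-overlapping discs on a dark
  background (plus optional sub-gate specks) for the dot counter.

All outputs are bit-for-bit reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_qc import CountMatrix, write_counts_mtx

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "KINETIC_ARCHETYPES",
    "simulate_bifurcation",
    "simulate_mixture",
    "make_signature",
    "simulate_dot_image",
    "write_dot_image",
    "write_simulation",
]

# archetype id -> (favored branch, baseline log-slope over the full axis)
KINETIC_ARCHETYPES: dict[int, tuple[str, float]] = {
    1: ("U", 0.0),
    2: ("L", 0.0),
    3: ("U", 1.5),
    4: ("L", 1.5),
    5: ("U", -1.5),
    6: ("L", -1.5),
}

_DEPOTS = ("supra", "peri", "subq", "visce")


@dataclass
class SimConfig:
    n_cells: int = 2000
    n_genes: int = 1000
    frac_branch_genes: float = 0.1
    divergence_times: tuple = (30.0, 60.0)
    effect_size: float = 1.0
    nb_dispersion: float = 0.5
    libsize_lognormal_sigma: float = 0.3
    mito_gene_count: int = 10
    dediff_fraction: float = 0.0
    seed: int = 0
    # structural knobs beyond the minimal surface
    split_time: float = 40.0
    branch_prop_u: float = 0.5
    base_libsize: float = 5000.0
    branch_gene_boost: float = 4.0
    baseline_slope_range: float = 0.75
    crossback_fraction: float = 0.0
    dediff_attenuation: float = 0.5
    mito_weight: float = 0.05
    n_archetypes: int = 6

    def __post_init__(self):
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise ValueError("n_cells and n_genes must be positive")
        for name in ("frac_branch_genes", "dediff_fraction",
                     "crossback_fraction", "dediff_attenuation",
                     "branch_prop_u", "mito_weight"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.divergence_times = tuple(float(t) for t in self.divergence_times)
        for t in self.divergence_times:
            if not 0.0 <= t <= 100.0:
                raise ValueError(f"divergence time {t} outside [0, 100]")
        if self.frac_branch_genes > 0 and not self.divergence_times:
            raise ValueError(
                "frac_branch_genes > 0 requires non-empty divergence_times")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.libsize_lognormal_sigma < 0:
            raise ValueError("libsize_lognormal_sigma must be >= 0")
        if self.mito_gene_count < 0:
            raise ValueError("mito_gene_count must be >= 0")
        if self.mito_gene_count >= self.n_genes:
            raise ValueError("mito_gene_count must be < n_genes")
        if not 0.0 < self.split_time < 100.0:
            raise ValueError("split_time must be inside (0, 100)")
        if not 1 <= self.n_archetypes <= len(KINETIC_ARCHETYPES):
            raise ValueError("n_archetypes out of range")


@dataclass
class SyntheticTruth:
    """Planted truth: per-gene branch effects and per-cell states."""

    genes: pd.DataFrame  # gene_id, is_branch_gene, favored_branch, t_star,
    #                      archetype, is_crossback
    cells: pd.DataFrame  # cell_id, true_branch, true_t, true_libsize, dediff
    config: SimConfig

    def branch_gene_ids(self) -> np.ndarray:
        return self.genes.loc[self.genes.is_branch_gene, "gene_id"].to_numpy()

    def to_json(self, path: str) -> None:
        payload = {
            "config": asdict(self.config),
            "genes": self.genes.to_dict(orient="list"),
            "cells": self.cells.to_dict(orient="list"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cfg = dict(payload["config"])
        cfg["divergence_times"] = tuple(cfg["divergence_times"])
        return cls(genes=pd.DataFrame(payload["genes"]),
                   cells=pd.DataFrame(payload["cells"]),
                   config=SimConfig(**cfg))


def _ramp(t: np.ndarray, t_star: float) -> np.ndarray:
    """Linear onset at t_star reaching 1 at the end of the axis."""
    denom = max(100.0 - t_star, 1e-9)
    return np.clip((t - t_star) / denom, 0.0, 1.0)


def _crossback(t: np.ndarray, t_star: float) -> np.ndarray:
    """Diverge after t_star, then cross back to a zero gap.

    Piecewise-linear profile on the rescaled tail
    u = (t - t_star)/(100 - t_star): rises to 1 by u = 0.25, returns to
    the shared baseline by u = 0.5 and stays there, so no maintained
    divergence survives to the end of the axis.
    """
    denom = max(100.0 - t_star, 1e-9)
    u = np.clip((t - t_star) / denom, 0.0, 1.0)
    return np.interp(u, [0.0, 0.25, 0.5, 1.0], [0.0, 1.0, 0.0, 0.0])


def simulate_bifurcation(config: SimConfig
                         ) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate bifurcating NB counts with planted divergence structure.

    Counts are negative-binomial (variance = mu + alpha * mu^2) with mean
    ``libsize_c * rho_g(t_c, branch_c) / sum_g rho_g``.  Baseline
    log-mean is linear in t; branch genes add ``effect_size`` times a
    ramp starting at the planted divergence time on the favored branch,
    so the between-branch gap is monotone non-decreasing after onset
    (crossback genes excepted, by design).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, g = cfg.n_cells, cfg.n_genes

    # --- cells -----------------------------------------------------------
    t = rng.uniform(0.0, 100.0, n)
    u_draw = rng.uniform(size=n)
    branch = np.where(t < cfg.split_time, "P",
                      np.where(u_draw < cfg.branch_prop_u, "U", "L"))
    branch = branch.astype(object)
    dediff = np.zeros(n, dtype=bool)
    if cfg.dediff_fraction > 0:
        late = np.where((t >= 70.0) & (branch != "P"))[0]
        k = int(round(cfg.dediff_fraction * len(late)))
        if k:
            chosen = rng.choice(late, size=k, replace=False)
            dediff[chosen] = True
            branch[chosen] = "P"
    libsize = cfg.base_libsize * np.exp(
        rng.normal(0.0, cfg.libsize_lognormal_sigma, n)
        - 0.5 * cfg.libsize_lognormal_sigma ** 2)

    # --- genes -----------------------------------------------------------
    n_mito = cfg.mito_gene_count
    gene_ids = np.array(
        [f"MT-G{i:04d}" for i in range(n_mito)]
        + [f"G{i:05d}" for i in range(n_mito, g)], dtype=object)
    mito_flags = np.zeros(g, dtype=bool)
    mito_flags[:n_mito] = True

    weights = rng.lognormal(0.0, 1.0, g)
    slopes = rng.uniform(-cfg.baseline_slope_range,
                         cfg.baseline_slope_range, g)

    # branch genes are planted in balanced U/L pairs: both members share
    # the weight, divergence time, shape and baseline slope, so the total
    # expression mass of the two branches is identical at every t and
    # per-cell normalization introduces no compositional U-vs-L artifact.
    n_branch = 2 * (int(round(cfg.frac_branch_genes * g)) // 2)
    non_mito = np.arange(n_mito, g)
    if n_branch > len(non_mito):
        raise ValueError("too many branch genes for the gene count")
    branch_idx = np.sort(rng.choice(non_mito, size=n_branch, replace=False))

    archetype = np.full(g, -1, dtype=int)
    favored = np.full(g, "", dtype=object)
    t_star = np.full(g, np.nan)
    is_cross = np.zeros(g, dtype=bool)
    n_pairs = n_branch // 2
    if n_pairs:
        n_families = max(1, round(cfg.n_archetypes / 2))
        pair_w = rng.lognormal(0.0, 1.0, n_pairs) * cfg.branch_gene_boost
        pair_t = rng.choice(np.asarray(cfg.divergence_times, dtype=float),
                            size=n_pairs)
        n_cross_pairs = int(round(cfg.crossback_fraction * n_pairs))
        cross_pairs = np.zeros(n_pairs, dtype=bool)
        if n_cross_pairs:
            cross_pairs[rng.choice(n_pairs, size=n_cross_pairs,
                                   replace=False)] = True
            # crossback genes need room to rise and return within the
            # axis: plant them at the earliest configured divergence time
            pair_t[cross_pairs] = min(cfg.divergence_times)
        fam = np.arange(n_pairs) % n_families
        arch_ids = np.empty(n_branch, dtype=int)
        arch_ids[0::2] = 2 * fam + 1   # U-favored member
        arch_ids[1::2] = 2 * fam + 2   # L-favored member
        weights[branch_idx] = np.repeat(pair_w, 2)
        archetype[branch_idx] = arch_ids
        favored[branch_idx] = [KINETIC_ARCHETYPES[a][0] for a in arch_ids]
        slopes[branch_idx] = [KINETIC_ARCHETYPES[a][1] for a in arch_ids]
        t_star[branch_idx] = np.repeat(pair_t, 2)
        is_cross[branch_idx] = np.repeat(cross_pairs, 2)
    if n_mito and cfg.mito_weight > 0:
        s_other = weights[n_mito:].sum()
        s_mito = weights[:n_mito].sum()
        target = cfg.mito_weight / (1.0 - cfg.mito_weight) * s_other
        weights[:n_mito] *= target / s_mito

    # --- mean matrix ------------------------------------------------------
    log_rho = np.log(weights)[None, :] + slopes[None, :] * (t[:, None] / 100.0)
    if cfg.effect_size > 0 and n_branch:
        for j in branch_idx:
            shape = _crossback(t, t_star[j]) if is_cross[j] \
                else _ramp(t, t_star[j])
            scale = (branch == favored[j]).astype(float)
            if cfg.dediff_fraction > 0:
                # dedifferentiated cells keep an attenuated fate memory
                scale = np.where(dediff, cfg.dediff_attenuation, scale)
            log_rho[:, j] += cfg.effect_size * shape * scale
    rho = np.exp(log_rho)
    mu = libsize[:, None] * rho / rho.sum(axis=1, keepdims=True)

    alpha = cfg.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mu)
    counts = rng.poisson(lam).astype(np.int64)

    cm = CountMatrix(values=sp.csr_matrix(counts), gene_ids=gene_ids,
                     cell_ids=np.array([f"cell{i:05d}" for i in range(n)],
                                       dtype=object),
                     mito_flags=mito_flags)

    timepoint = np.array([f"T{min(int(x // 20) + 1, 5)}" for x in t],
                         dtype=object)
    depot = rng.choice(np.asarray(_DEPOTS, dtype=object), size=n)
    meta = pd.DataFrame({
        "cell_id": cm.cell_ids,
        "depot": depot,
        "timepoint": timepoint,
        "umi_total": cm.umi_totals(),
        "n_genes": cm.genes_detected(),
        "mito_fraction": cm.mito_fractions(),
        "pseudotime_raw": t,
        "pseudotime_stretched": t,
        "branch": branch,
    })

    truth_genes = pd.DataFrame({
        "gene_id": gene_ids,
        "is_branch_gene": archetype > 0,
        "favored_branch": [f if f else None for f in favored],
        "t_star": t_star,
        "archetype": archetype,
        "is_crossback": is_cross,
    })
    truth_cells = pd.DataFrame({
        "cell_id": cm.cell_ids,
        "true_branch": branch,
        "true_t": t,
        "true_libsize": libsize,
        "dediff": dediff,
    })
    truth = SyntheticTruth(genes=truth_genes, cells=truth_cells, config=cfg)
    return cm, meta, truth


def make_signature(gene_ids=None, n_genes: int = 150, seed: int = 0
                   ) -> pd.DataFrame:
    """Two-column non-negative signature (brown/white) for tests and demos.

    Columns are scaled to a common total (mean 1 per gene) so that raw
    mixtures of the columns keep the mixing fraction identifiable under
    unit-sum fitting.
    """
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i:05d}" for i in range(10, 10 + n_genes)]
    gene_ids = list(gene_ids)
    brown = rng.lognormal(0.0, 1.0, len(gene_ids))
    white = rng.lognormal(0.0, 1.0, len(gene_ids))
    brown *= len(gene_ids) / brown.sum()
    white *= len(gene_ids) / white.sum()
    return pd.DataFrame({"brown": brown, "white": white},
                        index=pd.Index(gene_ids, name="gene"))


def simulate_mixture(signature: pd.DataFrame, fractions, noise_sd: float = 0.0,
                     seed: int = 0) -> pd.DataFrame:
    """Profiles ``f*brown + (1-f)*white + N(0, noise_sd)``, truncated at 0."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if signature.shape[1] != 2:
        raise ValueError("signature must have exactly two columns")
    fractions = np.asarray(list(fractions), dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    brown = signature.iloc[:, 0].to_numpy(dtype=float)
    white = signature.iloc[:, 1].to_numpy(dtype=float)
    cols = {}
    for i, f in enumerate(fractions):
        prof = f * brown + (1.0 - f) * white
        if noise_sd > 0:
            prof = prof + rng.normal(0.0, noise_sd, len(prof))
        cols[f"mix{i}"] = np.clip(prof, 0.0, None)
    return pd.DataFrame(cols, index=signature.index)


def simulate_dot_image(n_dots: int, radius_range=(4.0, 7.0),
                       image_shape=(256, 256), speck_count: int = 0,
                       noise_sd: float = 0.0, seed: int = 0,
                       max_tries: int = 20000
                       ) -> tuple[np.ndarray, int]:
    """Bright discs on a dark background; specks are isolated single pixels.

    Raises ``RuntimeError`` if the requested dots cannot be placed without
    overlap.  Returns the float image in [0, 1] and the planted count.
    """
    if n_dots < 0 or speck_count < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed)
    h, w = image_shape
    img = np.zeros((h, w), dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    placed: list[tuple[float, float, float]] = []
    for _ in range(n_dots):
        r = rng.uniform(*radius_range)
        for attempt in range(max_tries):
            y = rng.uniform(r + 1, h - r - 1)
            x = rng.uniform(r + 1, w - r - 1)
            if all(np.hypot(y - py, x - px) > r + pr + 2.0
                   for py, px, pr in placed):
                break
        else:
            raise RuntimeError(
                f"could not place {n_dots} non-overlapping dots in "
                f"{image_shape}")
        placed.append((y, x, r))
        brightness = rng.uniform(0.6, 1.0)
        disc = (yy - y) ** 2 + (xx - x) ** 2 <= r ** 2
        img[disc] = np.maximum(img[disc], brightness)
    speck_pos: list[tuple[int, int]] = []
    for _ in range(speck_count):
        for attempt in range(max_tries):
            y = int(rng.integers(1, h - 1))
            x = int(rng.integers(1, w - 1))
            if all(np.hypot(y - py, x - px) > pr + 3.0
                   for py, px, pr in placed) and \
               all(max(abs(y - sy), abs(x - sx)) > 2 for sy, sx in speck_pos):
                break
        else:
            raise RuntimeError("could not place specks without contact")
        speck_pos.append((y, x))
        img[y, x] = rng.uniform(0.6, 1.0)
    if noise_sd > 0:
        img = np.clip(img + rng.normal(0.0, noise_sd, img.shape), 0.0, 1.0)
    return img, n_dots


def write_dot_image(img: np.ndarray, path: str) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.round(np.clip(img, 0, 1) * 255).astype(np.uint8))


def write_simulation(cm: CountMatrix, meta: pd.DataFrame,
                     truth: SyntheticTruth, outdir: str) -> None:
    """Persist a simulation: MTX triplet, metadata CSV and truth JSON."""
    os.makedirs(outdir, exist_ok=True)
    write_counts_mtx(cm, outdir)
    meta.to_csv(os.path.join(outdir, "meta.csv"), index=False)
    truth.to_json(os.path.join(outdir, "truth.json"))
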