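"""Synthetic spatial transcriptomics generators.

Two study designs are emulated, both starting from a homogeneous Poisson
point process of cells on the unit square:

* design family ``sim1``: three circular spatial domains (D1 background,
  D2/D3 discs with radii U(0.1, 0.5) centered at randomly chosen cells),
  three cell types, 1000 genes with negative-binomial counts (mean 1,
  dispersion phi; variance mu + mu^2/phi), aggregated to a 0.03125 grid
  (1024 spots at full scale). Cases: ``sim1_null`` (markers + nulls),
  ``sim1_alt1`` (domain-specific genes: SVG and ctSVG), ``sim1_alt2``
  (complementary within-type patterns: ctSVG but not SVG), ``sim1_alt3``
  (domain-dependent cell-type mix: SVG but not ctSVG).
* design ``sim2``: 4000 cells, one spatially-variable disc domain SD
  (radius U(0.2, 0.4)) against background D, types at 10/30/60%,
  cell-type-specific fold changes inside SD, 0.05 grid (400 spots).

Every generator is a pure function of (config, seed). Cell-level counts are
conserved exactly under spot aggregation; empty grid cells are dropped
(they have no cells, hence no coordinates or composition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import SpatialDataset

__all__ = [
    "SimulationConfig",
    "CellLevelData",
    "simulate_cells",
    "assign_domains_sim1",
    "assign_domains_sim2",
    "assign_cell_types",
    "simulate_expression",
    "aggregate_to_spots",
    "misspecify_composition",
    "simulate_dataset",
]

SCENARIO_PROBS = {
    "s1": np.array([0.15, 0.15, 0.70]),
    "s2": np.array([0.30, 0.30, 0.40]),
    "s3": np.array([0.45, 0.45, 0.10]),
}
SIM2_PROBS = np.array([0.10, 0.30, 0.60])
FOLD_CHANGE_GROUPS = (4.0, 2.0, 0.5, 0.25)
N_GENES = 1000


@dataclass
class SimulationConfig:
    """Study-design parameters; defaults are the full-scale conditions."""

    design: str = "sim1_null"
    scenario: str = "s2"
    n_cells: int | None = None  # design default: 10000 (sim1) / 4000 (sim2)
    dispersion: float = 0.7
    base_mean: float = 1.0
    grid_size: float | None = None  # design default: 0.03125 / 0.05
    seed: int = 0
    misspecify: bool = False

    def __post_init__(self) -> None:
        if self.design not in {"sim1_null", "sim1_alt1", "sim1_alt2", "sim1_alt3", "sim2"}:
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "sim2":
            if self.scenario not in (None, "", "s2"):
                # sim2 has fixed 10/30/60 proportions
                raise ValueError("sim2 does not take a composition scenario")
        elif self.scenario not in SCENARIO_PROBS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_cells is None:
            self.n_cells = 4000 if self.design == "sim2" else 10000
        if self.grid_size is None:
            self.grid_size = 0.05 if self.design == "sim2" else 0.03125
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class CellLevelData:
    """Single-cell-resolution intermediate of a simulation run."""

    cell_coords: np.ndarray  # N x 2 in [0,1]^2
    domain_labels: np.ndarray  # int, 1-based
    type_labels: np.ndarray  # int in {1, 2, 3}
    counts: np.ndarray | None = None  # genes x cells
    gene_truth: "np.ndarray | None" = None  # structured per-gene labels
    domain_geometry: dict = field(default_factory=dict)


def simulate_cells(n_cells: int, seed: int) -> np.ndarray:
    """Homogeneous Poisson process on the unit square.

    The number of points is Poisson(n_cells) (the process intensity), the
    locations uniform — matching spatstat's rpoispp semantics rather than
    conditioning on an exact count.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    N = rng.poisson(n_cells)
    return rng.uniform(0.0, 1.0, size=(max(N, 2), 2))


def assign_domains_sim1(coords: np.ndarray, seed: int) -> tuple[np.ndarray, dict]:
    """Three domains: D1 background plus discs D2, D3 around random cells.

    Radii are drawn independently from U(0.1, 0.5); cells inside both
    discs join the domain with the smaller radius.
    """
    n = len(coords)
    if n < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(seed)
    centers = rng.choice(n, size=2, replace=False)
    radii = rng.uniform(0.1, 0.5, size=2)
    labels = np.ones(n, dtype=int)
    d2 = np.linalg.norm(coords - coords[centers[0]], axis=1) <= radii[0]
    d3 = np.linalg.norm(coords - coords[centers[1]], axis=1) <= radii[1]
    both = d2 & d3
    labels[d2] = 2
    labels[d3] = 3
    labels[both] = 2 if radii[0] <= radii[1] else 3
    geometry = {"centers": coords[centers].copy(), "radii": radii}
    return labels, geometry


def assign_domains_sim2(coords: np.ndarray, seed: int) -> tuple[np.ndarray, dict]:
    """Two domains: a disc SD (label 1, radius U(0.2, 0.4)) vs background D."""
    n = len(coords)
    rng = np.random.default_rng(seed)
    center = rng.integers(n)
    radius = rng.uniform(0.2, 0.4)
    inside = np.linalg.norm(coords - coords[center], axis=1) <= radius
    labels = np.where(inside, 1, 2)
    return labels, {"centers": coords[center : center + 1].copy(), "radii": np.array([radius])}


def assign_cell_types(
    domains: np.ndarray, design: str, scenario: str, seed: int
) -> np.ndarray:
    """Categorical cell-type draw; domain-conditional pairs for sim1_alt3."""
    rng = np.random.default_rng(seed)
    n = len(domains)
    if design == "sim1_alt3":
        # each domain hosts exactly two types at 50/50
        pairs = {1: (1, 2), 2: (2, 3), 3: (1, 3)}
        labels = np.empty(n, dtype=int)
        for dom, (a, b) in pairs.items():
            mask = domains == dom
            labels[mask] = rng.choice([a, b], size=mask.sum())
        return labels
    if design == "sim2":
        probs = SIM2_PROBS
    else:
        probs = SCENARIO_PROBS[scenario]
    return rng.choice([1, 2, 3], size=n, p=probs)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB with variance mu + mu^2/phi (size phi); fold change 0 -> exact 0."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = phi / (phi + mean[pos])
        out[pos] = rng.negative_binomial(phi, p)
    return out


def _marker_truth(n_marker: int, per_type: int, fc: float) -> list[dict]:
    rows = []
    for g in range(n_marker):
        rows.append({"role": "marker", "cell_type": g // per_type + 1, "fold_change": fc})
    return rows


def simulate_expression(
    cells: CellLevelData, design: str, dispersion: float, seed: int, base_mean: float = 1.0
) -> CellLevelData:
    """Negative-binomial cell-level counts for 1000 genes with the design's
    gene partition (markers / spatial genes / nulls) and fold changes."""
    rng = np.random.default_rng(seed)
    n = len(cells.type_labels)
    types = cells.type_labels
    doms = cells.domain_labels
    mu0 = base_mean
    phi = dispersion
    means = np.full((N_GENES, n), mu0)
    truth: list[dict] = []

    def null_rows(count):
        return [{"role": "null", "cell_type": 0, "fold_change": 1.0} for _ in range(count)]

    if design in {"sim1_null", "sim1_alt1", "sim1_alt2"}:
        # 300 cell-type marker genes, 100 per type, fold change 4
        for g in range(300):
            means[g, types == (g // 100 + 1)] = mu0 * 4.0
        truth += _marker_truth(300, 100, 4.0)

    if design == "sim1_null":
        truth += null_rows(700)
    elif design == "sim1_alt1":
        # 600 domain-specific genes: 200 per domain in FC groups of 50
        for g in range(300, 900):
            j = g - 300
            dom = j // 200 + 1
            fc = FOLD_CHANGE_GROUPS[(j % 200) // 50]
            means[g, doms == dom] = mu0 * fc
            truth.append({"role": "svg", "cell_type": 0, "fold_change": fc, "domain": dom})
        truth += null_rows(100)
    elif design == "sim1_alt2":
        # 700 ctSVGs with complementary patterns for types 1 and 2;
        # type 3 is the flat reference (baseline mean everywhere)
        t1, t2 = types == 1, types == 2
        in_d1, in_d2 = doms == 1, doms == 2
        for g in range(300, 1000):
            means[g, t1 & in_d1] = mu0 * 2.0
            means[g, t1 & in_d2] = 0.0
            means[g, t2 & in_d1] = 0.0
            means[g, t2 & in_d2] = mu0 * 2.0
            truth.append({"role": "ctsvg", "cell_type": 0, "fold_change": 2.0})
    elif design == "sim1_alt3":
        # 600 cell-type marker genes, 200 per type, FC groups of 50;
        # spatial pattern arises purely from the domain-dependent type mix
        for g in range(600):
            k = g // 200 + 1
            fc = FOLD_CHANGE_GROUPS[(g % 200) // 50]
            means[g, types == k] = mu0 * fc
            truth.append({"role": "svg_marker", "cell_type": k, "fold_change": fc})
        truth += null_rows(400)
    elif design == "sim2":
        # 300 markers (FC 2), then 600 ctSVGs: 200 per type, FC groups of
        # 50 applied to cells of that type inside domain SD
        for g in range(300):
            means[g, types == (g // 100 + 1)] = mu0 * 2.0
        truth += _marker_truth(300, 100, 2.0)
        in_sd = doms == 1
        for g in range(300, 900):
            j = g - 300
            k = j // 200 + 1
            fc = FOLD_CHANGE_GROUPS[(j % 200) // 50]
            means[g, (types == k) & in_sd] = mu0 * fc
            truth.append({"role": "ctsvg", "cell_type": k, "fold_change": fc})
        truth += null_rows(100)
    else:
        raise ValueError(f"unknown design {design!r}")

    counts = _nb_draw(rng, means, phi)
    cells.counts = counts
    cells.gene_truth = np.array(
        [(t["role"], t["cell_type"], t["fold_change"]) for t in truth],
        dtype=[("role", "U12"), ("cell_type", "i4"), ("fold_change", "f8")],
    )
    return cells


def aggregate_to_spots(cells: CellLevelData, grid_size: float) -> SpatialDataset:
    """Sum cell counts over a regular grid; spot coordinate = member-cell
    centroid; composition = member-type fractions; empty cells dropped."""
    if cells.counts is None:
        raise ValueError("simulate_expression must run before aggregation")
    coords = cells.cell_coords
    m = int(np.ceil(1.0 / grid_size))
    ix = np.minimum((coords[:, 0] / grid_size).astype(int), m - 1)
    iy = np.minimum((coords[:, 1] / grid_size).astype(int), m - 1)
    spot_of_cell = ix * m + iy
    occupied, inverse = np.unique(spot_of_cell, return_inverse=True)
    n_spots = len(occupied)
    q = cells.counts.shape[0]
    counts = np.zeros((q, n_spots))
    np.add.at(counts.T, inverse, cells.counts.T)
    spot_coords = np.zeros((n_spots, 2))
    np.add.at(spot_coords, inverse, coords)
    n_cells_per_spot = np.bincount(inverse, minlength=n_spots).astype(float)
    spot_coords /= n_cells_per_spot[:, None]
    K = int(cells.type_labels.max())
    comp = np.zeros((n_spots, K))
    np.add.at(comp, (inverse, cells.type_labels - 1), 1.0)
    comp /= n_cells_per_spot[:, None]
    return SpatialDataset(
        counts=counts,
        coords=spot_coords,
        composition=comp,
        gene_ids=[f"gene_{i}" for i in range(q)],
        spot_ids=[f"spot_{s}" for s in occupied],
        cell_type_ids=[f"type_{k + 1}" for k in range(K)],
    )


def misspecify_composition(ds: SpatialDataset, seed: int) -> SpatialDataset:
    """Replace the composition by 4 fake types, rows ~ Dirichlet(1,1,1,1).

    Emulates feeding the model the output of "a terrible deconvolution
    tool"; the original composition is the ground truth held elsewhere.
    """
    rng = np.random.default_rng(seed)
    comp = rng.dirichlet(np.ones(4), size=ds.n_spots)
    return SpatialDataset(
        counts=ds.counts.copy(),
        coords=ds.coords.copy(),
        composition=comp,
        covariates=ds.covariates.copy(),
        normalized=None if ds.normalized is None else ds.normalized.copy(),
        gene_ids=list(ds.gene_ids),
        spot_ids=list(ds.spot_ids),
        cell_type_ids=[f"fake_{k + 1}" for k in range(4)],
    )


def simulate_dataset(config: SimulationConfig) -> tuple[SpatialDataset, CellLevelData]:
    """Run the full generator pipeline for one replicate.

    Independent sub-streams are derived from ``config.seed`` so each stage
    (point process, domains, types, expression) is reproducible on its own.
    """
    ss = np.random.SeedSequence(config.seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss]
    coords = simulate_cells(config.n_cells, seeds[0])
    if config.design == "sim2":
        domains, geom = assign_domains_sim2(coords, seeds[1])
    else:
        domains, geom = assign_domains_sim1(coords, seeds[1])
    types = assign_cell_types(domains, config.design, config.scenario, seeds[2])
    cells = CellLevelData(
        cell_coords=coords,
        domain_labels=domains,
        type_labels=types,
        domain_geometry=geom,
    )
    cells = simulate_expression(
        cells, config.design, config.dispersion, seeds[3], config.base_mean
    )
    ds = aggregate_to_spots(cells, config.grid_size)
    if config.misspecify:
        ds = misspecify_composition(ds, seeds[4])
    return ds, cells
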