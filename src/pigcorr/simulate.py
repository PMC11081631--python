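"""Synthetic paired image–transcriptome studies with known ground truth.

Every downstream stage of the pipeline is testable without any download:
this module fabricates (i) z-stack cell images whose in-disk intensity
encodes a known pigment level, (ii) negative-binomial count matrices in
which named genes carry a prescribed Pearson correlation with normalized
brightness, (iii) gene-set collections with planted and decoy sets, and
(iv) multi-lineage study bundles tying these together.

Image model: each pixel has a shared gray base (background level, dimmed
inside the cell disk by ``pigment_level``), per-plane additive jitter,
shared Gaussian pixel noise, and a small independent per-channel noise —
so the three channels are nearly identical by construction, reproducing
the r > 0.99 inter-channel correlation that justifies a single brightness
proxy.

Count model: gene g in cell c is NB(mean = m·exp(βz_c − β²/2), dispersion
θ) where z is standardized Ynorm. The slope β is calibrated from the
variance decomposition r = β_y/√(β_y² + σ²) on the log-normalized scale,
evaluated exactly through the NB conditional moments and solved by
root-finding, so the realized correlation of log-normalized expression
with Ynorm converges to ``target_rho`` as the cohort grows.

All randomness flows from one root seed via named substreams, so a bundle
is byte-identical across reruns and partial reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .brightness import brightness_record
from .enrichment import GeneSet, GeneSetCollection
from .expression import CountMatrix
from .image_color import CellColorRecord, RoiSpec, ZStackImage

__all__ = [
    "ImageSimParams",
    "PlantedGeneSpec",
    "NBParams",
    "PlantedSetConfig",
    "StudyConfig",
    "StudyBundle",
    "LineageData",
    "generate_cell_image",
    "expected_delta",
    "calibrate_slope",
    "generate_counts",
    "generate_gene_sets",
    "generate_study",
    "pigment_to_ynorm",
]


@dataclass(frozen=True)
class ImageSimParams:
    """Geometry and noise of one simulated cell image stack.

    The canvas geometry (400×330 px, 21 planes, cell disk of radius 50 px
    at (195, 169)) mirrors the imaging setup the pipeline expects. The
    expected in-disk intensity is ``background_level × (1 − pigment_level
    × depth_factor)``; outside the disk it is ``background_level``.
    """

    canvas_width: int = 400
    canvas_height: int = 330
    n_planes: int = 21
    cell_center: tuple[float, float] = (195.0, 169.0)
    cell_radius: float = 50.0
    background_level: float = 200.0
    pigment_level: float = 0.5
    depth_factor: float = 1.0
    noise_sd: float = 2.0
    plane_jitter_sd: float = 1.0
    channel_noise_sd: float = 0.5
    seed: int | tuple = 0

    def validate(self) -> None:
        cx, cy = self.cell_center
        if (
            cx - self.cell_radius < 0
            or cy - self.cell_radius < 0
            or cx + self.cell_radius > self.canvas_width - 1
            or cy + self.cell_radius > self.canvas_height - 1
        ):
            raise ValueError("cell disk extends beyond the canvas")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must lie in [0, 255]")
        if not 0 <= self.pigment_level <= 1:
            raise ValueError("pigment_level must lie in [0, 1]")
        if self.n_planes < 1:
            raise ValueError("n_planes must be >= 1")

    @property
    def roi(self) -> RoiSpec:
        return RoiSpec(
            center_x=self.cell_center[0],
            center_y=self.cell_center[1],
            radius=self.cell_radius,
        )


def generate_cell_image(params: ImageSimParams, cell_id: str = "") -> ZStackImage:
    """Render one z-stack; deterministic given ``params.seed``."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.canvas_height, params.canvas_width
    base = np.full((h, w), params.background_level, dtype=float)
    mask = params.roi.mask(h, w)
    base[mask] = params.background_level * (
        1.0 - params.pigment_level * params.depth_factor
    )
    planes = np.empty((params.n_planes, h, w, 3), dtype=np.uint8)
    for p in range(params.n_planes):
        shared = base
        if params.noise_sd > 0:
            shared = shared + rng.normal(0.0, params.noise_sd, size=(h, w))
        jitter = rng.normal(0.0, params.plane_jitter_sd) if params.plane_jitter_sd > 0 else 0.0
        plane = shared[..., None] + jitter
        if params.channel_noise_sd > 0:
            plane = plane + rng.normal(0.0, params.channel_noise_sd, size=(h, w, 3))
        else:
            plane = np.broadcast_to(plane, (h, w, 3))
        planes[p] = np.clip(np.rint(plane), 0, 255).astype(np.uint8)
    return ZStackImage(planes=planes, cell_id=cell_id)


def expected_delta(params: ImageSimParams) -> np.ndarray:
    """Noise-free background-subtracted intensity (equal across channels)."""
    d = -params.background_level * params.pigment_level * params.depth_factor
    return np.full(3, d)


def pigment_to_ynorm(
    pigment, background_level: float = 200.0, depth_factor: float = 1.0,
    proxy: str = "luma",
) -> np.ndarray:
    """Analytic Ynorm for given pigment levels (the generator's ground truth)."""
    pigment = np.atleast_1d(np.asarray(pigment, dtype=float))
    out = np.empty_like(pigment)
    for i, p in enumerate(pigment):
        rec = brightness_record(
            f"_p{i}", np.full(3, -background_level * p * depth_factor), proxy=proxy
        )
        out[i] = rec.Ynorm
    return out


# ---------------------------------------------------------------------------
# counts


@dataclass(frozen=True)
class PlantedGeneSpec:
    """Truth container: a gene with a prescribed expression–brightness r."""

    gene_id: str
    target_rho: float
    baseline_mean: float = 10.0
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        if not abs(self.target_rho) < 1:
            raise ValueError("|target_rho| must be < 1")
        if not self.baseline_mean > 0:
            raise ValueError("baseline_mean must be positive")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class NBParams:
    """Background-gene negative-binomial parameters (means log-uniform)."""

    mean_low: float = 0.2
    mean_high: float = 20.0
    dispersion: float = 2.0


_calibration_cache: dict = {}


def _predicted_r(
    beta: float, m0: float, theta: float, z: np.ndarray, total: float,
    scale_factor: float,
) -> float:
    """Pearson r of log-normalized NB expression with z, from exact moments."""
    mu = m0 * np.exp(beta * z - 0.5 * beta * beta)
    mu_max = float(mu.max())
    cutoff = int(sps.nbinom.ppf(1 - 1e-10, theta, theta / (theta + mu_max))) + 2
    if cutoff > 200_000:
        raise ValueError("calibration diverges: NB support cutoff too large")
    k = np.arange(cutoff)
    y = np.log1p(k * scale_factor / total)
    pmf = sps.nbinom.pmf(k[:, None], theta, theta / (theta + mu[None, :]))
    m1 = y @ pmf
    m2 = (y * y) @ pmf
    cond_var = np.maximum(m2 - m1 * m1, 0.0)
    signal_var = m1.var()
    total_var = signal_var + cond_var.mean()
    if total_var == 0:
        return 0.0
    cov = np.mean(m1 * z) - m1.mean() * z.mean()
    return float(cov / (np.sqrt(total_var) * z.std()))


def calibrate_slope(
    target_rho: float,
    baseline_mean: float,
    dispersion: float,
    z: np.ndarray,
    expected_total: float,
    scale_factor: float = 1e4,
    max_slope: float = 12.0,
) -> float:
    """Solve for the log-mean slope β yielding the target Pearson r.

    Raises ValueError when the target is unreachable for the given
    dispersion (the predicted r saturates below |target_rho|).
    """
    z = np.asarray(z, dtype=float)
    key = (
        round(target_rho, 12), round(baseline_mean, 12), round(dispersion, 12),
        round(expected_total, 6), round(scale_factor, 6), z.tobytes(),
    )
    if key in _calibration_cache:
        return _calibration_cache[key]
    if target_rho == 0:
        _calibration_cache[key] = 0.0
        return 0.0

    def f(beta: float) -> float:
        return (
            _predicted_r(beta, baseline_mean, dispersion, z, expected_total, scale_factor)
            - target_rho
        )

    sign = 1.0 if target_rho > 0 else -1.0
    lo, hi = 0.0, sign * 0.5
    while f(hi) * sign < 0:
        hi *= 2.0
        if abs(hi) > max_slope:
            raise ValueError(
                f"target_rho={target_rho} unreachable with dispersion="
                f"{dispersion}: calibration diverges"
            )
    beta = optimize.brentq(f, min(lo, hi), max(lo, hi), xtol=1e-4)
    _calibration_cache[key] = float(beta)
    return float(beta)


def generate_counts(
    ynorm_values,
    planted,
    n_background_genes: int,
    nb_params: NBParams | None = None,
    seed: int | tuple = 0,
    scale_factor: float = 1e4,
    cell_ids=None,
    background_prefix: str = "BG",
) -> tuple[CountMatrix, pd.DataFrame]:
    """NB count matrix with planted brightness-correlated genes.

    Planted genes appear as the first rows (order of ``planted``),
    followed by ``n_background_genes`` genes independent of brightness.
    Returns the matrix and a truth table (gene_id, target_rho, slope,
    baseline_mean, dispersion).
    """
    nb_params = nb_params or NBParams()
    y = np.asarray(ynorm_values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("ynorm_values must be finite")
    if n_background_genes < 0:
        raise ValueError("n_background_genes must be >= 0")
    planted = list(planted)
    n = len(y)
    if cell_ids is None:
        cell_ids = [f"cell_{i:05d}" for i in range(n)]

    if planted:
        sd = y.std()
        if sd == 0 and any(p.target_rho != 0 for p in planted):
            raise ValueError("constant ynorm: cannot plant nonzero correlations")
        z = (y - y.mean()) / (sd if sd > 0 else 1.0)
    else:
        z = np.zeros(n)

    rng_bg = np.random.default_rng(_seed_seq(seed, 1))
    rng_pl = np.random.default_rng(_seed_seq(seed, 2))

    bg_means = np.exp(
        rng_bg.uniform(np.log(nb_params.mean_low), np.log(nb_params.mean_high),
                       size=n_background_genes)
    )
    # design-expected library size (mean of the log-uniform), not the realized
    # draw: keeps the slope calibration a function of the design alone
    lo, hi = nb_params.mean_low, nb_params.mean_high
    bg_mean_expected = (hi - lo) / np.log(hi / lo) if hi > lo else lo
    expected_total = float(
        n_background_genes * bg_mean_expected + sum(p.baseline_mean for p in planted)
    )
    if expected_total <= 0:
        expected_total = 1.0  # degenerate empty matrix; normalization unused

    blocks, truth_rows = [], []
    for spec in planted:
        beta = calibrate_slope(
            spec.target_rho, spec.baseline_mean, spec.dispersion, z,
            expected_total, scale_factor,
        )
        mu = spec.baseline_mean * np.exp(beta * z - 0.5 * beta * beta)
        counts = rng_pl.negative_binomial(
            spec.dispersion, spec.dispersion / (spec.dispersion + mu)
        )
        blocks.append(counts)
        truth_rows.append(
            {
                "gene_id": spec.gene_id,
                "target_rho": spec.target_rho,
                "slope": beta,
                "baseline_mean": spec.baseline_mean,
                "dispersion": spec.dispersion,
            }
        )
    if n_background_genes:
        theta = nb_params.dispersion
        bg_counts = rng_bg.negative_binomial(
            theta, theta / (theta + bg_means[:, None]), size=(n_background_genes, n)
        )
    else:
        bg_counts = np.zeros((0, n), dtype=np.int64)

    genes = [p.gene_id for p in planted] + [
        f"{background_prefix}{i:05d}" for i in range(n_background_genes)
    ]
    counts = (
        np.vstack([np.vstack(blocks), bg_counts]) if blocks else bg_counts
    )
    if not genes:
        counts = np.zeros((0, n), dtype=np.int64)
    cm = CountMatrix(genes=genes, cells=list(cell_ids), counts=counts)
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "target_rho", "slope", "baseline_mean", "dispersion"],
    )
    return cm, truth


def _seed_seq(seed, *extra: int) -> np.random.SeedSequence:
    """Named substream: flatten (seed, *extra) into one entropy list."""
    base = list(seed) if isinstance(seed, (tuple, list)) else [int(seed)]
    return np.random.SeedSequence(base + list(extra))


# ---------------------------------------------------------------------------
# gene sets


def generate_gene_sets(
    planted_sets,
    decoy_sets: int,
    universe,
    seed: int | tuple = 0,
    size_range: tuple[int, int] = (15, 100),
    decoy_prefix: str = "DECOY_",
) -> GeneSetCollection:
    """Planted sets plus random decoy sets drawn from the universe."""
    universe = list(universe)
    if not universe:
        raise ValueError("empty gene universe")
    uni = set(universe)
    col = GeneSetCollection()
    for name, members in dict(planted_sets).items():
        members = list(members)
        outside = [m for m in members if m not in uni]
        if outside:
            raise ValueError(f"planted set {name!r} has members outside the universe: "
                             f"{outside[:5]}")
        col.add(GeneSet(name=name, description="planted", genes=tuple(members)))
    rng = np.random.default_rng(_seed_seq(seed, 3))
    lo, hi = size_range
    hi = min(hi, len(universe))
    for i in range(decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(universe), size=size, replace=False)
        col.add(
            GeneSet(
                name=f"{decoy_prefix}{i:03d}",
                description="decoy",
                genes=tuple(universe[j] for j in members),
            )
        )
    return col


# ---------------------------------------------------------------------------
# study bundles


@dataclass(frozen=True)
class PlantedSetConfig:
    """One gene set whose members all share a target brightness correlation."""

    name: str = "PIGMENT_RESPONSE"
    n_genes: int = 30
    target_rho: float = 0.5
    baseline_mean: float = 10.0
    dispersion: float = 2.0


@dataclass(frozen=True)
class StudyConfig:
    """The simulated study design: three lineages of picked cells by default."""

    lineages: tuple[str, ...] = ("Lonza-RPE", "iPS201-RPE", "iPS253-RPE")
    cells_per_lineage: int = 96
    n_genes: int = 2000
    planted_sets: tuple[PlantedSetConfig, ...] = (PlantedSetConfig(),)
    n_decoy_sets: int = 50
    decoy_size_range: tuple[int, int] = (15, 100)
    pigment_range: tuple[float, float] = (0.1, 0.9)
    background_nb: NBParams = NBParams()
    image: ImageSimParams = ImageSimParams()
    with_images: bool = False
    scale_factor: float = 1e4

    def __post_init__(self) -> None:
        if len(self.lineages) < 1:
            raise ValueError("config must name at least one lineage")
        lo, hi = self.pigment_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("pigment_range must lie within [0, 1]")


@dataclass
class LineageData:
    name: str
    metadata: pd.DataFrame  # cell_id, lineage, pigment, image_path
    counts: CountMatrix
    true_ynorm: np.ndarray
    truth: pd.DataFrame
    image_params: list[ImageSimParams] | None = None

    def iter_images(self):
        """Lazily regenerate each cell's z-stack (seeded, byte-identical)."""
        if self.image_params is None:
            raise ValueError(f"lineage {self.name!r} was simulated without images")
        for cell_id, p in zip(self.metadata["cell_id"], self.image_params):
            yield generate_cell_image(p, cell_id=cell_id)


@dataclass
class StudyBundle:
    config: StudyConfig
    seed: int
    lineages: dict[str, LineageData]
    gene_sets: GeneSetCollection
    planted_set_names: list[str]
    planted_genes: pd.DataFrame  # gene_id, set_name, target_rho


def generate_study(config: StudyConfig, seed: int = 0) -> StudyBundle:
    """Simulate a full multi-lineage study with shared planted structure.

    Every lineage uses the same gene universe and the same planted gene
    sets (members correlated with brightness in each lineage), so the
    cross-lineage intersection has a known answer.
    """
    planted_specs: list[PlantedGeneSpec] = []
    planted_rows = []
    planted_members: dict[str, list[str]] = {}
    for sc in config.planted_sets:
        members = [f"{sc.name}_G{j:03d}" for j in range(sc.n_genes)]
        planted_members[sc.name] = members
        for g in members:
            planted_specs.append(
                PlantedGeneSpec(
                    gene_id=g,
                    target_rho=sc.target_rho,
                    baseline_mean=sc.baseline_mean,
                    dispersion=sc.dispersion,
                )
            )
            planted_rows.append(
                {"gene_id": g, "set_name": sc.name, "target_rho": sc.target_rho}
            )
    n_planted = len(planted_specs)
    n_bg = config.n_genes - n_planted
    if n_bg < 0:
        raise ValueError("n_genes smaller than the number of planted genes")

    lineages: dict[str, LineageData] = {}
    universe: list[str] | None = None
    for li, lineage in enumerate(config.lineages):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 10 + li]))
        npc = config.cells_per_lineage
        pigment = rng.uniform(*config.pigment_range, size=npc)
        cell_ids = [f"{lineage}_c{j:04d}" for j in range(npc)]
        true_ynorm = pigment_to_ynorm(
            pigment,
            background_level=config.image.background_level,
            depth_factor=config.image.depth_factor,
        )
        image_params = None
        if config.with_images:
            image_params = [
                replace(
                    config.image,
                    pigment_level=float(p),
                    seed=(seed, 20 + li, j),
                )
                for j, p in enumerate(pigment)
            ]
        counts, truth = generate_counts(
            true_ynorm,
            planted_specs,
            n_background_genes=n_bg,
            nb_params=config.background_nb,
            seed=(seed, 30 + li),
            scale_factor=config.scale_factor,
            cell_ids=cell_ids,
        )
        if universe is None:
            universe = list(counts.genes)
        metadata = pd.DataFrame(
            {
                "cell_id": cell_ids,
                "lineage": lineage,
                "pigment": pigment,
                "image_path": "",
            }
        )
        lineages[lineage] = LineageData(
            name=lineage,
            metadata=metadata,
            counts=counts,
            true_ynorm=true_ynorm,
            truth=truth,
            image_params=image_params,
        )

    gene_sets = generate_gene_sets(
        planted_members,
        decoy_sets=config.n_decoy_sets,
        universe=universe or [],
        seed=(seed, 40),
        size_range=config.decoy_size_range,
    )
    return StudyBundle(
        config=config,
        seed=seed,
        lineages=lineages,
        gene_sets=gene_sets,
        planted_set_names=list(planted_members),
        planted_genes=pd.DataFrame(
            planted_rows, columns=["gene_id", "set_name", "target_rho"]
        ),
    )
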