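"""Synthetic inputs with the statistical structure the analyses assume.

Three generators, all seeded and deterministic:

* :func:`simulate_read_table` — a fecal-metabarcoding OTU table.  Each
  sample belongs to a habitat group (restored / alternative); each prey
  taxon occurs in a sample with a group-specific Bernoulli probability, and
  reads for the occurring taxa are drawn multinomially from
  Dirichlet-perturbed mean read shares (a single ``dispersion`` knob
  controls overdispersion).  A reserved ``HOST_SELF`` OTU receives a
  configurable share of reads in expectation, so host-DNA exclusion is
  testable.  Every occurring taxon is guaranteed at least one read, so a
  planted occurrence probability is exactly the expected frequency of
  occurrence.

* :func:`simulate_habitat_table` — per-site water chemistry, habitat shape
  summaries and egg-sac counts as multivariate normal draws from a planted
  correlation matrix (egg-sac counts are a rounded, zero-truncated latent
  Gaussian; with count means well above zero the attenuation of the planted
  Pearson structure is negligible).

* :func:`simulate_polygon` — site outlines of prescribed shape (circle,
  ellipse, rectangle, blob) as radial polygons, so any noise level still
  yields a simple (star-shaped) polygon.

The default diet roster and correlation structure mirror the study
conditions this package is built around: 18 samples per habitat group,
~150k reads per sample, twelve prey families whose occurrence probabilities
differ between groups, and the published 10-variable site correlation
matrix (which is positive definite and can be planted verbatim).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError
from .otu_io import HOST_TAXON_ID, UNCLASSIFIED, ReadMatrix

__all__ = [
    "TaxonSpec",
    "DietSimConfig",
    "HabitatSimConfig",
    "ShapeSimConfig",
    "DEFAULT_TAXA",
    "DEFAULT_SITE_CORRELATION",
    "default_habitat_config",
    "simulate_read_table",
    "simulate_habitat_table",
    "simulate_polygon",
    "write_fixtures",
]


@dataclass(frozen=True)
class TaxonSpec:
    """Planted per-taxon parameters, one per prey taxon."""

    taxon_id: str
    family: str
    occurrence_prob_restored: float
    occurrence_prob_alternative: float
    mean_read_share_restored: float
    mean_read_share_alternative: float


#: default prey roster: occurrence probabilities echo the published
#: restored-vs-alternative frequency-of-occurrence contrasts
DEFAULT_TAXA: tuple[TaxonSpec, ...] = (
    TaxonSpec("Perlidae_sp", "Perlidae", 0.50, 0.71, 0.08, 0.12),
    TaxonSpec("Chironomidae_sp", "Chironomidae", 0.29, 0.35, 0.10, 0.06),
    TaxonSpec("Psychodidae_sp", "Psychodidae", 0.50, 0.30, 0.09, 0.04),
    TaxonSpec("Tubificidae_sp", "Tubificidae", 0.14, 0.59, 0.03, 0.09),
    TaxonSpec("Nematocera_sp", "Nematocera", 0.40, 0.45, 0.07, 0.06),
    TaxonSpec("Pentatomatidae_sp", "Pentatomatidae", 0.36, 0.30, 0.06, 0.04),
    TaxonSpec("Ranidae_sp", "Ranidae", 0.21, 0.53, 0.02, 0.04),
    TaxonSpec("Lymnaeidae_sp", "Lymnaeidae", 0.10, 0.30, 0.01, 0.03),
    TaxonSpec("Hydropsychidae_sp", "Hydropsychidae", 0.10, 0.15, 0.01, 0.02),
    TaxonSpec("Carabidae_sp", "Carabidae", 0.05, 0.05, 0.005, 0.005),
    TaxonSpec("Libellulidae_sp", "Libellulidae", 0.10, 0.10, 0.01, 0.01),
    TaxonSpec("Physella_acuta", "Physidae", 0.0, 0.18, 0.0, 0.02),
)


@dataclass
class DietSimConfig:
    """Configuration of the diet-table generator (defaults = study design)."""

    n_samples_per_group: int = 18
    taxa: tuple[TaxonSpec, ...] = DEFAULT_TAXA
    reads_per_sample: int = 150_000
    host_contamination_share: float = 0.5
    dispersion: float = 50.0
    primer: str = "18SV9"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_group < 1:
            raise ConfigError("n_samples_per_group must be >= 1")
        if self.reads_per_sample < 1:
            raise ConfigError("reads_per_sample must be >= 1")
        if not 0 <= self.host_contamination_share < 1:
            raise ConfigError("host_contamination_share must be in [0, 1)")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        for group in ("restored", "alternative"):
            total = 0.0
            for t in self.taxa:
                occ = getattr(t, f"occurrence_prob_{group}")
                share = getattr(t, f"mean_read_share_{group}")
                if not 0 <= occ <= 1:
                    raise ConfigError(f"{t.taxon_id}: occurrence_prob_{group} "
                                      f"{occ} outside [0, 1]")
                if not 0 <= share <= 1:
                    raise ConfigError(f"{t.taxon_id}: mean_read_share_{group} "
                                      f"{share} outside [0, 1]")
                total += share
            if total > 1 + 1e-12:
                raise ConfigError(f"group {group!r}: mean read shares sum to "
                                  f"{total:.4f} > 1")


def simulate_read_table(config: DietSimConfig) -> tuple[ReadMatrix, pd.DataFrame]:
    """Generate an OTU read table plus its taxonomy map.

    Returns a :class:`~salamet.otu_io.ReadMatrix` (samples x OTUs, one OTU
    per taxon plus the host OTU and an 'Unclassified/Other' remainder
    column) and a taxonomy DataFrame indexed by otu_id with columns taxon,
    family, is_host.
    """
    rng = np.random.default_rng(config.seed)
    taxa = list(config.taxa)
    otu_ids = [t.taxon_id for t in taxa] + [UNCLASSIFIED, HOST_TAXON_ID]
    sample_rows = []
    counts = np.zeros((2 * config.n_samples_per_group, len(otu_ids)), dtype=np.int64)

    for g_idx, group in enumerate(("restored", "alternative")):
        occ = np.array([getattr(t, f"occurrence_prob_{group}") for t in taxa])
        share = np.array([getattr(t, f"mean_read_share_{group}") for t in taxa])
        other_share = max(0.0, 1.0 - share.sum())
        prefix = "R" if group == "restored" else "A"
        for s in range(config.n_samples_per_group):
            row = g_idx * config.n_samples_per_group + s
            sample_rows.append((f"{prefix}{s + 1:02d}", group, config.primer))
            present = rng.random(len(taxa)) < occ
            shares = np.append(share[present], other_share)  # Unclassified always present
            if shares.sum() <= 0:
                shares = np.ones_like(shares)
            shares = shares / shares.sum()
            alpha = np.maximum(config.dispersion * shares, 1e-6)
            p = rng.dirichlet(alpha)
            host_reads = rng.binomial(config.reads_per_sample,
                                      config.host_contamination_share)
            prey_total = config.reads_per_sample - host_reads
            k = len(shares)
            # one guaranteed read per occurring taxon, remainder multinomial
            if prey_total < k:
                prey_total = k
                host_reads = max(0, config.reads_per_sample - k)
            draw = np.ones(k, dtype=np.int64)
            draw += rng.multinomial(prey_total - k, p)
            cols = np.append(np.nonzero(present)[0], len(taxa))
            counts[row, cols] = draw
            counts[row, -1] = host_reads

    sample_ids = [r[0] for r in sample_rows]
    meta = pd.DataFrame(
        {"habitat_type": [r[1] for r in sample_rows],
         "primer": [r[2] for r in sample_rows]},
        index=pd.Index(sample_ids, name="sample_id"))
    matrix = ReadMatrix(pd.DataFrame(counts, index=meta.index, columns=otu_ids), meta)
    taxonomy = pd.DataFrame(
        {"taxon": [t.taxon_id for t in taxa] + [UNCLASSIFIED, "Hynobius_yangi"],
         "family": [t.family for t in taxa] + ["unknown", "Hynobiidae"],
         "is_host": [False] * (len(taxa) + 1) + [True]},
        index=pd.Index(otu_ids, name="otu_id"))
    return matrix, taxonomy


# ---------------------------------------------------------------------------
# habitat site tables

_SITE_VARS = ("egg_sac", "temp_C", "pH", "do_mgL", "do_pct", "conductivity_uScm",
              "alkalinity_mgL_CaCO3", "turbidity_NTU", "area_m2", "circularity_pct")

#: planted correlation structure of the ten site variables (response first);
#: positive definite (min eigenvalue ~ 0.013)
DEFAULT_SITE_CORRELATION = np.array([
    # egg    temp     pH   do_mg  do_pct   cond    alk    turb   area   circ
    [1.000, -0.158, -0.232, -0.041, -0.082, -0.211, -0.125, 0.028, -0.205, -0.061],
    [-0.158, 1.000, 0.224, -0.048, 0.275, 0.445, 0.057, 0.026, 0.187, -0.054],
    [-0.232, 0.224, 1.000, 0.707, 0.736, 0.466, 0.292, 0.051, 0.472, -0.206],
    [-0.041, -0.048, 0.707, 1.000, 0.932, 0.213, 0.107, 0.019, 0.278, -0.142],
    [-0.082, 0.275, 0.736, 0.932, 1.000, 0.335, 0.135, 0.025, 0.300, -0.134],
    [-0.211, 0.445, 0.466, 0.213, 0.335, 1.000, 0.441, -0.047, 0.249, -0.240],
    [-0.125, 0.057, 0.292, 0.107, 0.135, 0.441, 1.000, 0.128, 0.165, -0.265],
    [0.028, 0.026, 0.051, 0.019, 0.025, -0.047, 0.128, 1.000, -0.022, 0.099],
    [-0.205, 0.187, 0.472, 0.278, 0.300, 0.249, 0.165, -0.022, 1.000, -0.243],
    [-0.061, -0.054, -0.206, -0.142, -0.134, -0.240, -0.265, 0.099, -0.243, 1.000],
])

_DEFAULT_MEANS = (40.0, 13.0, 7.55, 11.1, 105.0, 53.0, 18.5, 8.6, 115.5, 44.2)
_DEFAULT_SDS = (12.0, 3.5, 0.45, 1.4, 11.0, 12.0, 5.0, 7.0, 70.0, 11.0)


@dataclass
class HabitatSimConfig:
    """Configuration of the site-table generator."""

    n_sites: int = 125
    variable_names: tuple[str, ...] = _SITE_VARS
    target_correlation: np.ndarray = field(
        default_factory=lambda: DEFAULT_SITE_CORRELATION.copy())
    means: tuple[float, ...] = _DEFAULT_MEANS
    sds: tuple[float, ...] = _DEFAULT_SDS
    seed: int = 0

    def __post_init__(self) -> None:
        C = np.asarray(self.target_correlation, dtype=float)
        k = len(self.variable_names)
        if C.shape != (k, k) or len(self.means) != k or len(self.sds) != k:
            raise ConfigError("correlation/means/sds dimensions inconsistent")
        if not np.allclose(C, C.T, atol=1e-10) or not np.allclose(np.diag(C), 1.0):
            raise ConfigError("target correlation must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ConfigError("target correlation matrix is not positive semi-definite")
        if any(s <= 0 for s in self.sds):
            raise ConfigError("sds must all be positive")
        if self.n_sites < 2:
            raise ConfigError("n_sites must be >= 2")
        self.target_correlation = C


def simulate_habitat_table(config: HabitatSimConfig) -> pd.DataFrame:
    """Per-site table of chemistry, shape summaries and egg-sac counts.

    Multivariate normal draws through an eigenfactorization of the planted
    correlation matrix, scaled to the configured means/sds; the egg_sac
    column (if present) is rounded and truncated at zero.  A habitat_type
    column is assigned at random (half restored, half alternative).
    """
    rng = np.random.default_rng(config.seed)
    C = config.target_correlation
    w, V = np.linalg.eigh(C)
    factor = V * np.sqrt(np.clip(w, 0.0, None))
    Z = rng.standard_normal((config.n_sites, len(config.variable_names)))
    X = Z @ factor.T
    X = X * np.asarray(config.sds) + np.asarray(config.means)
    df = pd.DataFrame(X, columns=list(config.variable_names),
                      index=pd.Index([f"S{i + 1:03d}" for i in range(config.n_sites)],
                                     name="site_id"))
    if "egg_sac" in df.columns:
        df["egg_sac"] = np.maximum(np.rint(df["egg_sac"]), 0).astype(int)
    habitat = np.where(rng.random(config.n_sites) < 0.5, "restored", "alternative")
    df.insert(0, "habitat_type", habitat)
    return df


# ---------------------------------------------------------------------------
# site outlines

@dataclass
class ShapeSimConfig:
    """Configuration of the outline generator (radial polygons)."""

    shape_kind: str = "circle"
    size_param: float = 10.0
    n_vertices: int = 256
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape_kind not in ("circle", "ellipse", "rectangle", "blob"):
            raise ConfigError(f"unknown shape_kind {self.shape_kind!r}")
        if self.size_param <= 0:
            raise ConfigError("size_param must be positive")
        if self.n_vertices < 3:
            raise ConfigError("n_vertices must be >= 3")
        if self.noise < 0:
            raise ConfigError("noise must be >= 0")


def simulate_polygon(config: ShapeSimConfig) -> np.ndarray:
    """A closed simple polygon of the requested shape as an (n, 2) array.

    All shapes are generated as radial functions r(theta) around the origin
    with multiplicative radial noise clipped away from zero, so the result
    is star-shaped and therefore always simple.
    """
    rng = np.random.default_rng(config.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, config.n_vertices, endpoint=False)
    a = config.size_param
    if config.shape_kind == "circle":
        r = np.full_like(theta, a)
    elif config.shape_kind == "ellipse":
        b = a / 2.0
        r = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    elif config.shape_kind == "rectangle":
        # square of side 2a centred at the origin
        r = a / np.maximum(np.abs(np.cos(theta)), np.abs(np.sin(theta)))
    else:  # blob: smooth random radial harmonics
        r = np.full_like(theta, a)
        for harmonic in range(2, 6):
            amp = rng.uniform(0.0, 0.25) * a
            phase = rng.uniform(0.0, 2.0 * np.pi)
            r = r + amp * np.cos(harmonic * theta + phase)
        r = np.maximum(r, 0.05 * a)
    if config.noise > 0:
        r = r * np.maximum(1.0 + config.noise * rng.standard_normal(len(theta)), 0.05)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


# ---------------------------------------------------------------------------
# fixture materialization

def write_fixtures(outdir, seed: int = 0, diet: DietSimConfig | None = None,
                   habitat: HabitatSimConfig | None = None,
                   n_polygons: int = 6) -> dict[str, str]:
    """Write a complete demo dataset (all pipeline input formats) to a
    directory; returns the mapping of artifact name -> path."""
    from . import geometry

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    diet = diet if diet is not None else DietSimConfig(seed=seed)
    habitat = habitat if habitat is not None else HabitatSimConfig(seed=seed + 1)

    matrix, taxonomy = simulate_read_table(diet)
    paths = {"otu_table": str(out / "otu_table.tsv"),
             "taxonomy": str(out / "taxonomy.tsv"),
             "metadata": str(out / "metadata.tsv"),
             "sites": str(out / "sites.tsv"),
             "reference": str(out / "reference.tsv")}
    matrix.counts.to_csv(paths["otu_table"], sep="\t", index_label="sample_id")
    taxonomy.to_csv(paths["taxonomy"], sep="\t", index_label="otu_id")
    matrix.sample_meta.to_csv(paths["metadata"], sep="\t", index_label="sample_id")
    simulate_habitat_table(habitat).to_csv(paths["sites"], sep="\t")

    # benthic-invertebrate field reference: availability loosely tracking the
    # alternative-group occurrence, plus survey-only families
    rng = np.random.default_rng(seed + 2)
    rows = []
    for t in diet.taxa:
        count = int(rng.poisson(200 * max(t.occurrence_prob_alternative, 0.02)))
        if count:
            rows.append((t.family, "benthic", count))
    rows.append(("Ephemerellidae", "benthic", 40))  # survey-only family -> D = -1
    pd.DataFrame(rows, columns=["family", "group", "count"]).to_csv(
        paths["reference"], sep="\t", index=False)

    shapes = ("circle", "ellipse", "rectangle", "blob")
    poly_dir = out / "polygons"
    poly_dir.mkdir(exist_ok=True)
    for i in range(n_polygons):
        cfg = ShapeSimConfig(shape_kind=shapes[i % len(shapes)],
                             size_param=10.0 + 3.0 * i, n_vertices=128,
                             noise=0.01, seed=seed + 10 + i)
        p = poly_dir / f"site_{i + 1:02d}.txt"
        geometry.write_polygon(p, simulate_polygon(cfg))
        paths[f"polygon_{i + 1}"] = str(p)
    return paths
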