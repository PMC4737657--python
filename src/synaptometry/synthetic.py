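"""Synthetic neuropil generator.

Emulates the statistical structure of a hippocampal CA1 spine population as
measured by dense 3DEM reconstruction, so every downstream stage of the
pipeline can be exercised without any imaging data:

* a right-skewed (log-normal) head-volume population spanning roughly a
  60-fold size range;
* power-law cross-metric couplings — head area tracking volume almost
  deterministically (r² ≈ 0.99), PSD area and docked-vesicle count strongly
  but noisily coupled, neck diameter weakly coupled, neck length uncoupled;
* axon-coupled same-dendrite spine pairs whose members are multiplicative
  jitters of a common base size, calibrated so the median per-pair CV of
  head volume is 0.083;
* presynaptic vesicle clouds with a constructed docked subset defined by
  the 100-nm membrane-distance rule; and
* watertight toy spine meshes (spherical head + cylindrical neck) with
  ground-truth region tags and analytic volumes for the morphometry oracle.

A single integer seed expands into fixed per-component substreams, so each
stage is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import ConfigurationError, DomainError, SizingError, TaggingError
from .mesh import TaggedMesh
from .records import SpineRecord, SpinePair, VesicleCloud

__all__ = [
    "MetricCoupling",
    "PopulationConfig",
    "PairConfig",
    "DEFAULT_COUPLINGS",
    "MEDIAN_ABS_STANDARD_NORMAL",
    "generate_population",
    "calibrate_within_pair_sd",
    "median_pair_cv_for_sd",
    "generate_coupled_pairs",
    "generate_spine_mesh",
    "generate_vesicle_cloud",
    "component_rng",
]

#: median of |Z| for Z ~ N(0, 1)
MEDIAN_ABS_STANDARD_NORMAL = 0.6744897501960817

# fixed substream offsets: one seed reproduces every stage in isolation
_STREAM_OFFSETS = {"population": 0, "pairs": 1, "vesicles": 2, "null": 3, "release": 4}


def component_rng(seed: int, component: str) -> np.random.Generator:
    """Per-component RNG substream derived from a single top-level seed."""
    if component not in _STREAM_OFFSETS:
        raise ConfigurationError(f"unknown RNG component {component!r}")
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM_OFFSETS[component],)))


@dataclass(frozen=True)
class MetricCoupling:
    """Power-law link metric = prefactor · V^exponent · exp(ε), ε ~ N(0, log_noise_sd)."""

    exponent: float
    prefactor: float
    log_noise_sd: float

    def validate(self, name: str) -> None:
        if self.log_noise_sd < 0:
            raise ConfigurationError(
                f"metric_coupling[{name!r}].log_noise_sd must be >= 0, "
                f"got {self.log_noise_sd}")
        if self.prefactor <= 0:
            raise ConfigurationError(
                f"metric_coupling[{name!r}].prefactor must be > 0, got {self.prefactor}")


#: Default couplings. Head area tracks volume near-deterministically with a
#: surface-like 2/3 exponent; PSD area and docked vesicles are strongly but
#: noisily coupled; neck diameter only weakly; neck length not at all.
#: Prefactors are set so the medians at V = 0.03 µm³ are realistic for CA1
#: stratum radiatum (head area ~0.56 µm², PSD ~0.013 µm², neck ~0.15 µm
#: diameter × 0.66 µm length, ~15 docked vesicles per bouton).
DEFAULT_COUPLINGS: dict[str, MetricCoupling] = {
    "head_area": MetricCoupling(exponent=2.0 / 3.0, prefactor=5.8, log_noise_sd=0.04),
    "psd_area": MetricCoupling(exponent=0.85, prefactor=0.25, log_noise_sd=0.25),
    "neck_diameter": MetricCoupling(exponent=0.10, prefactor=0.213, log_noise_sd=0.30),
    "neck_length": MetricCoupling(exponent=0.0, prefactor=0.66, log_noise_sd=0.55),
    "docked_vesicles": MetricCoupling(exponent=0.80, prefactor=248.0, log_noise_sd=0.35),
}


@dataclass
class PopulationConfig:
    """Parameters of the synthetic spine population.

    ``log_sigma`` is the sd of the natural log of head volume; the default
    0.6 makes the median CV of randomly paired spines ≈ 0.39 and a 287-spine
    sample span a few tens of fold in head volume (median max/min ratio ≈ 30
    over seeds). ``range_factor_target`` records the nominal dynamic range
    the population is meant to represent; it is carried into the capacity
    stage, not enforced sample-by-sample.
    """

    n_spines: int = 287
    median_head_volume: float = 0.03   # µm³
    log_sigma: float = 0.6
    range_factor_target: float = 60.0
    metric_coupling: dict[str, MetricCoupling] = field(
        default_factory=lambda: dict(DEFAULT_COUPLINGS))
    spines_per_dendrite: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.n_spines < 2:
            raise ConfigurationError(f"n_spines must be >= 2, got {self.n_spines}")
        if not self.log_sigma > 0:
            raise ConfigurationError(f"log_sigma must be > 0, got {self.log_sigma}")
        if not self.range_factor_target > 1:
            raise ConfigurationError(
                f"range_factor_target must be > 1, got {self.range_factor_target}")
        if not self.median_head_volume > 0:
            raise ConfigurationError(
                f"median_head_volume must be > 0, got {self.median_head_volume}")
        for name, coupling in self.metric_coupling.items():
            coupling.validate(name)


@dataclass
class PairConfig:
    """Axon-coupled pair generation parameters.

    Exactly one of ``within_pair_log_sd`` (σδ, the sd of the log-ratio of
    the two members) and ``target_median_pair_cv`` may be given; the other
    is derived through :func:`calibrate_within_pair_sd`.
    """

    n_pairs: int = 17
    within_pair_log_sd: float | None = None
    target_median_pair_cv: float | None = 0.083
    seed: int = 0

    def validate(self) -> None:
        if self.n_pairs < 0:
            raise ConfigurationError(f"n_pairs must be >= 0, got {self.n_pairs}")
        if (self.within_pair_log_sd is None) == (self.target_median_pair_cv is None):
            raise ConfigurationError(
                "exactly one of within_pair_log_sd / target_median_pair_cv "
                "must be set")
        if self.within_pair_log_sd is not None and self.within_pair_log_sd < 0:
            raise ConfigurationError(
                f"within_pair_log_sd must be >= 0, got {self.within_pair_log_sd}")

    def resolved_log_sd(self) -> float:
        self.validate()
        if self.within_pair_log_sd is not None:
            return self.within_pair_log_sd
        return calibrate_within_pair_sd(self.target_median_pair_cv)


# ---------------------------------------------------------------------------
# population


def _derive_metrics(head_volumes: np.ndarray, couplings: dict[str, MetricCoupling],
                    rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Sample all dependent metrics given head volumes via the power-law model."""
    out: dict[str, np.ndarray] = {}
    v = np.asarray(head_volumes, float)
    for name, c in couplings.items():
        mu = c.prefactor * v ** c.exponent
        if c.log_noise_sd > 0:
            mu = mu * np.exp(rng.normal(0.0, c.log_noise_sd, size=v.shape))
        if name == "docked_vesicles":
            out[name] = rng.poisson(mu).astype(int)
        else:
            out[name] = mu
    return out


def generate_population(config: PopulationConfig) -> list[SpineRecord]:
    """Sample a synthetic spine table. Deterministic given ``config.seed``.

    Head volumes are log-normal(ln median, log_sigma); every other metric is
    a power law of head volume with log-normal noise per the config's
    couplings (neck length has exponent 0, i.e. is independent). Neck volume
    is the cylinder π(d/2)²L and whole-spine volume = head + neck, so the
    subtraction identity holds by construction.
    """
    config.validate()
    rng = component_rng(config.seed, "population")
    n = config.n_spines
    head_volume = np.exp(rng.normal(math.log(config.median_head_volume),
                                    config.log_sigma, size=n))
    metrics = _derive_metrics(head_volume, config.metric_coupling, rng)
    neck_volume = np.pi * (metrics["neck_diameter"] / 2.0) ** 2 * metrics["neck_length"]
    whole = head_volume + neck_volume
    records = []
    per_dendrite = max(1, config.spines_per_dendrite)
    for i in range(n):
        records.append(SpineRecord(
            spine_id=f"spine_{i:04d}",
            dendrite_id=f"dendrite_{i // per_dendrite:03d}",
            axon_id=f"axon_{i:04d}",
            head_volume=float(head_volume[i]),
            head_area=float(metrics["head_area"][i]),
            psd_area=float(metrics["psd_area"][i]),
            neck_length=float(metrics["neck_length"][i]),
            neck_diameter=float(metrics["neck_diameter"][i]),
            neck_volume=float(neck_volume[i]),
            whole_spine_volume=float(whole[i]),
            docked_vesicles=int(metrics["docked_vesicles"][i]),
        ))
    return records


# ---------------------------------------------------------------------------
# pair calibration


def median_pair_cv_for_sd(log_sd: float) -> float:
    """Median per-pair CV when members are v·e^{±δ/2}, δ ~ N(0, log_sd).

    For such a pair the CV is exactly √2·tanh(|δ|/2), a monotone map of
    |δ|, so the median CV is √2·tanh(median|δ|/2) with
    median|δ| = 0.6745·log_sd.
    """
    if log_sd < 0:
        raise DomainError(f"log_sd must be >= 0, got {log_sd}")
    return math.sqrt(2.0) * math.tanh(MEDIAN_ABS_STANDARD_NORMAL * log_sd / 2.0)


def calibrate_within_pair_sd(target_median_cv: float) -> float:
    """Invert :func:`median_pair_cv_for_sd`: σδ achieving a target median CV.

    Closed form σδ = 2·atanh(target/√2)/0.6745. Target 0.083 → σδ ≈ 0.174.
    """
    if target_median_cv == 0:
        return 0.0
    if not 0 < target_median_cv < 1:
        raise DomainError(
            f"target median pair CV must be in (0, 1), got {target_median_cv}")
    return 2.0 * math.atanh(target_median_cv / math.sqrt(2.0)) / MEDIAN_ABS_STANDARD_NORMAL


# ---------------------------------------------------------------------------
# coupled pairs


def generate_coupled_pairs(records: list[SpineRecord], config: PairConfig,
                           couplings: dict[str, MetricCoupling] | None = None,
                           ) -> tuple[list[SpinePair], list[SpineRecord]]:
    """Plant axon-coupled same-dendrite pairs into a spine population.

    Base sizes are drawn (with replacement) from the population's empirical
    head-volume distribution; the two members get volumes v·e^{+δ/2} and
    v·e^{−δ/2} with δ ~ N(0, σδ), so their geometric mean is the base size
    and the population distribution is preserved. Dependent metrics of the
    pair members are regenerated from the coupling model at the new volumes.
    Both members share an axon and a dendrite; all remaining spines keep
    unique axons. Returns the pairs and the updated record table.
    """
    if not records:
        raise SizingError("population is empty")
    config.validate()
    if 2 * config.n_pairs > len(records):
        raise SizingError(
            f"need {2 * config.n_pairs} spines for {config.n_pairs} pairs, "
            f"population has {len(records)}")
    couplings = dict(DEFAULT_COUPLINGS if couplings is None else couplings)
    rng = component_rng(config.seed, "pairs")
    log_sd = config.resolved_log_sd()

    volumes = np.array([r.head_volume for r in records])
    base = rng.choice(volumes, size=config.n_pairs, replace=True)
    delta = rng.normal(0.0, log_sd, size=config.n_pairs) if log_sd > 0 else np.zeros(config.n_pairs)
    member_volumes = np.empty(2 * config.n_pairs)
    member_volumes[0::2] = base * np.exp(+delta / 2.0)
    member_volumes[1::2] = base * np.exp(-delta / 2.0)
    metrics = _derive_metrics(member_volumes, couplings, rng)
    neck_vol = np.pi * (metrics["neck_diameter"] / 2.0) ** 2 * metrics["neck_length"]

    new_records: list[SpineRecord] = []
    pairs: list[SpinePair] = []
    for i, rec in enumerate(records):
        if i < 2 * config.n_pairs:
            k = i // 2
            new_records.append(SpineRecord(
                spine_id=rec.spine_id,
                dendrite_id=f"pair_dendrite_{k:03d}",
                axon_id=f"pair_axon_{k:03d}",
                head_volume=float(member_volumes[i]),
                head_area=float(metrics["head_area"][i]),
                psd_area=float(metrics["psd_area"][i]),
                neck_length=float(metrics["neck_length"][i]),
                neck_diameter=float(metrics["neck_diameter"][i]),
                neck_volume=float(neck_vol[i]),
                whole_spine_volume=float(member_volumes[i] + neck_vol[i]),
                docked_vesicles=int(metrics["docked_vesicles"][i]),
            ))
        else:
            new_records.append(SpineRecord(
                spine_id=rec.spine_id, dendrite_id=rec.dendrite_id,
                axon_id=f"axon_{i:04d}", head_volume=rec.head_volume,
                head_area=rec.head_area, psd_area=rec.psd_area,
                neck_length=rec.neck_length, neck_diameter=rec.neck_diameter,
                neck_volume=rec.neck_volume,
                whole_spine_volume=rec.whole_spine_volume,
                docked_vesicles=rec.docked_vesicles))
    for k in range(config.n_pairs):
        pairs.append(SpinePair(spine_a=new_records[2 * k], spine_b=new_records[2 * k + 1],
                               same_dendrite=True, multi_contact=False))
    return pairs, new_records


# ---------------------------------------------------------------------------
# toy spine mesh


def generate_spine_mesh(head_volume: float, neck_length: float, neck_diameter: float,
                        *, subdivisions: int = 4, psd_polar_angle: float = 0.45,
                        allow_zero_neck: bool = False, name: str = "spine",
                        ) -> TaggedMesh:
    """Watertight toy spine: spherical head joined to a cylindrical neck.

    The head is a latitude/longitude sphere of radius R = (3V/4π)^{1/3}
    truncated where the neck attaches; the neck is a cylinder of the given
    diameter and length, capped at the far end. The sphere/cylinder boundary
    ring is shared, so the mesh is closed and manifold by construction.
    ``subdivisions`` controls resolution (rows = 6·2^s, columns = 8·2^s).

    Regions: ``head`` (truncated sphere), ``neck`` (cylinder + cap),
    ``whole_spine`` (everything), and a polar cap of half-angle
    ``psd_polar_angle`` tagged both ``psd`` and ``active_zone`` (the apposed
    membranes coincide in this toy geometry). Analytic ground truths
    (head/neck volume, psd area) are stored on the mesh.
    """
    if head_volume <= 0 or neck_diameter <= 0:
        raise DomainError("head_volume and neck_diameter must be > 0")
    if neck_length < 0 or (neck_length == 0 and not allow_zero_neck):
        raise DomainError("neck_length must be > 0 (pass allow_zero_neck=True "
                          "for a headless-neck fixture)")
    radius = (3.0 * head_volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    neck_r = neck_diameter / 2.0
    if neck_r >= 0.95 * radius:
        raise DomainError(
            f"neck radius {neck_r} too large for head radius {radius}; "
            "the neck must attach inside the sphere")

    n_rows = 6 * 2 ** subdivisions
    n_phi = 8 * 2 ** subdivisions
    theta_max = math.pi - math.asin(neck_r / radius)   # polar angle of the junction ring
    z_ring = radius * math.cos(theta_max)

    phis = np.linspace(0.0, 2.0 * math.pi, n_phi, endpoint=False)
    thetas = np.linspace(0.0, theta_max, n_rows + 1)[1:]   # exclude the pole itself

    verts = [np.array([0.0, 0.0, radius])]                  # north pole
    for th in thetas:
        r_ring = radius * math.sin(th)
        z = radius * math.cos(th)
        verts.extend(np.column_stack([r_ring * np.cos(phis),
                                      r_ring * np.sin(phis),
                                      np.full(n_phi, z)]))
    ring_start = 1 + (n_rows - 1) * n_phi   # first vertex of the junction ring

    faces = []
    # pole fan
    for j in range(n_phi):
        faces.append([0, 1 + j, 1 + (j + 1) % n_phi])
    # sphere bands
    for i in range(n_rows - 1):
        a0 = 1 + i * n_phi
        b0 = 1 + (i + 1) * n_phi
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            faces.append([a0 + j, b0 + j, b0 + jn])
            faces.append([a0 + j, b0 + jn, a0 + jn])
    n_head_faces = len(faces)

    if neck_length > 0:
        bottom_start = len(verts)
        z_bot = z_ring - neck_length
        verts.extend(np.column_stack([neck_r * np.cos(phis),
                                      neck_r * np.sin(phis),
                                      np.full(n_phi, z_bot)]))
        for j in range(n_phi):
            jn = (j + 1) % n_phi
            faces.append([ring_start + j, bottom_start + j, bottom_start + jn])
            faces.append([ring_start + j, bottom_start + jn, ring_start + jn])
        center = len(verts)
        verts.append(np.array([0.0, 0.0, z_bot]))
        for j in range(n_phi):
            faces.append([center, bottom_start + (j + 1) % n_phi, bottom_start + j])
    else:
        center = len(verts)
        verts.append(np.array([0.0, 0.0, z_ring]))
        for j in range(n_phi):
            faces.append([center, ring_start + (j + 1) % n_phi, ring_start + j])

    mesh = trimesh.Trimesh(vertices=np.vstack(verts), faces=np.asarray(faces),
                           process=False)
    mesh.fix_normals()

    all_faces = np.arange(len(mesh.faces))
    head_faces = all_faces[:n_head_faces]
    neck_faces = all_faces[n_head_faces:]
    centroids = mesh.triangles.mean(axis=1)
    polar = np.arccos(np.clip(centroids[:, 2] / np.linalg.norm(centroids, axis=1),
                              -1.0, 1.0))
    psd_faces = all_faces[(polar < psd_polar_angle) & (all_faces < n_head_faces)]

    cap_height = radius + z_ring   # height of the spherical cap replaced by the neck
    cap_volume = math.pi * cap_height ** 2 * (3 * radius - cap_height) / 3.0
    truth = {
        "head_radius": radius,
        "head_volume": head_volume - cap_volume,     # truncated sphere + flat disk
        "neck_volume": math.pi * neck_r ** 2 * neck_length + cap_volume,
        "psd_area": 2.0 * math.pi * radius ** 2 * (1.0 - math.cos(psd_polar_angle)),
    }
    tagged = TaggedMesh(mesh=mesh, name=name, ground_truth=truth, region_tags={
        "head": head_faces,
        "neck": neck_faces,
        "whole_spine": all_faces,
        "psd": psd_faces,
        "active_zone": psd_faces,
    })
    tagged.validate()
    return tagged


# ---------------------------------------------------------------------------
# vesicle cloud


def generate_vesicle_cloud(n_vesicles: int, mesh: TaggedMesh,
                           docked_fraction_target: float, seed: int,
                           *, threshold_nm: float = 100.0, boundary_margin_nm: float = 1.0,
                           far_max_nm: float = 600.0) -> VesicleCloud:
    """Place vesicle centers around a mesh's active zone with known docked labels.

    A ``docked_fraction_target`` share of centers is placed along outward
    active-zone normals at distances uniform in
    [boundary_margin, threshold − boundary_margin] nm, the rest at
    [threshold + boundary_margin·50, far_max] nm, so ground truth is fixed
    at construction and no center sits on the threshold boundary.
    """
    if n_vesicles < 0:
        raise SizingError(f"n_vesicles must be >= 0, got {n_vesicles}")
    if not 0 <= docked_fraction_target <= 1:
        raise DomainError("docked_fraction_target must be in [0, 1]")
    if not mesh.has_region("active_zone"):
        raise TaggingError(f"mesh {mesh.name!r} has no 'active_zone' region")
    if n_vesicles == 0:
        return VesicleCloud(centers_nm=np.zeros((0, 3)),
                            docked_truth=np.zeros(0, dtype=bool),
                            associated_spine_id=mesh.name)

    rng = component_rng(seed, "vesicles")
    faces = mesh.region_faces("active_zone")
    tris = mesh.mesh.triangles[faces]                       # µm
    areas = mesh.mesh.area_faces[faces]
    normals = mesh.mesh.face_normals[faces]

    n_docked = int(round(n_vesicles * docked_fraction_target))
    pick = rng.choice(len(faces), size=n_vesicles, p=areas / areas.sum())
    # uniform barycentric sample on each picked triangle
    r1 = np.sqrt(rng.uniform(size=n_vesicles))
    r2 = rng.uniform(size=n_vesicles)
    a, b, c = tris[pick, 0], tris[pick, 1], tris[pick, 2]
    surface = (1 - r1)[:, None] * a + (r1 * (1 - r2))[:, None] * b + (r1 * r2)[:, None] * c

    offsets_nm = np.empty(n_vesicles)
    near_hi = threshold_nm - boundary_margin_nm
    offsets_nm[:n_docked] = rng.uniform(boundary_margin_nm, near_hi, size=n_docked)
    offsets_nm[n_docked:] = rng.uniform(threshold_nm + 50.0 * boundary_margin_nm,
                                        far_max_nm, size=n_vesicles - n_docked)
    centers_um = surface + normals[pick] * (offsets_nm / 1000.0)[:, None]
    labels = np.zeros(n_vesicles, dtype=bool)
    labels[:n_docked] = True
    return VesicleCloud(centers_nm=centers_um * 1000.0, docked_truth=labels,
                        associated_spine_id=mesh.name)
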