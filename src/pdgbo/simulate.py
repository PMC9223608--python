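"""Synthetic data with known ground truth for every pipeline stage.

This module emulates the study conditions of a patient-derived glioblastoma
organoid (PD-GBO) functional screen:

* a 384-pillar drug screen — 41 drugs in duplicate, fourfold seven-point
  dilutions from 30 µM, DMSO vehicle wells and a bortezomib-like positive
  control — with latent four-parameter-logistic (4PL) dose–response and
  multiplicative lognormal readout noise;
* organoid image phantoms — nuclei as disks, a nestin-positive
  tumor-microtube network as anti-aliased filaments plus soma rings, and a
  calcein channel whose intensity scales with per-cell viability — rendered
  into 16-bit z-stacks;
* calcium traces sampled at 1.52 s/frame in which network-connected cells
  share transient times (instant rise, exponential decay) up to small jitter;
* expression matrices with planted pathway shifts that covary with drug
  sensitivity, for testing enrichment/correlation recovery.

All generators draw from a single explicit seed; truth parameters are part
of the dataclasses so downstream tests can compare against ground truth.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imaging import OrganoidImageSet

__all__ = [
    "DrugTruth",
    "ScreenTruth",
    "ImageTruth",
    "CalciumTruth",
    "ExpressionTruth",
    "four_pl",
    "make_dilution_series",
    "make_plate_layout",
    "make_screen_truth",
    "simulate_viability",
    "make_image_truth",
    "render_organoid_images",
    "make_calcium_truth",
    "simulate_calcium_traces",
    "make_expression_truth",
    "simulate_expression",
]

PLATE_ROWS = string.ascii_uppercase[:16]  # A..P
PLATE_COLS = 24
PLATE_WELLS = len(PLATE_ROWS) * PLATE_COLS  # 384

POSITIVE_CONTROL_ID = "bortezomib"


# --------------------------------------------------------------------------
# Truth containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DrugTruth:
    """Latent 4PL parameters of one drug (viability fractions)."""

    top: float = 1.0
    bottom: float = 1.0  # flat (inactive) by default
    ic50: float = 1e-6  # molar
    hill: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.bottom <= self.top):
            raise ValueError("require 0 <= bottom <= top")
        if self.ic50 <= 0 or self.hill <= 0:
            raise ValueError("ic50 and hill must be positive")


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen: per-drug curves + noise model."""

    drugs: dict[str, DrugTruth]
    hits: frozenset[str] = frozenset()
    sigma: float = 0.05  # lognormal sd on viability (multiplicative)
    baseline: float = 10000.0  # vehicle fluorescence-area level
    plate_sigma: float = 0.02  # lognormal sd of per-plate baseline factor
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.plate_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")
        missing = self.hits - set(self.drugs)
        if missing:
            raise ValueError(f"hit flags for unknown drugs: {sorted(missing)}")


@dataclass
class ImageTruth:
    """Geometric phantom of one organoid field.

    centers: (N, 2) array of (row, col) pixel coordinates; radii: nuclear
    radii in px; adjacency: symmetric list of connected cell index pairs
    (tumor-microtube filaments); viability in [0, 1] per cell.
    """

    centers: np.ndarray
    radii: np.ndarray
    adjacency: list[tuple[int, int]]
    viability: np.ndarray
    shape: tuple[int, int, int] = (512, 512, 5)  # H, W, Z
    bit_depth: int = 16
    filament_width: float = 3.0
    soma_ring_width: float = 2.0
    calcein_scale: float = 1.6  # cytoplasm radius = calcein_scale * nuclear radius

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if self.centers.size == 0:
            self.centers = self.centers.reshape(0, 2)
        self.radii = np.asarray(self.radii, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.bit_depth != 16:
            raise ValueError("only 16-bit rendering is supported")
        h, w, _ = self.shape
        if len(self.centers) and (
            (self.centers[:, 0] < 0).any()
            or (self.centers[:, 1] < 0).any()
            or (self.centers[:, 0] >= h).any()
            or (self.centers[:, 1] >= w).any()
        ):
            raise ValueError("all cell centers must lie inside the image")
        for i, j in self.adjacency:
            if i == j:
                raise ValueError("self-loop in adjacency")
        # keep adjacency symmetric and deduplicated as unordered pairs
        pairs = {tuple(sorted(p)) for p in self.adjacency}
        self.adjacency = sorted(pairs)

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    # Analytic (anti-aliasing-free) ground-truth masks -----------------

    def nuclei_mask(self) -> np.ndarray:
        h, w, _ = self.shape
        mask = np.zeros((h, w), dtype=bool)
        for (r, c), rad in zip(self.centers, self.radii):
            mask |= _disk_mask((h, w), (r, c), rad)
        return mask

    def nestin_mask(self) -> np.ndarray:
        h, w, _ = self.shape
        mask = np.zeros((h, w), dtype=bool)
        for i, j in self.adjacency:
            mask |= _segment_mask(
                (h, w), self.centers[i], self.centers[j], self.filament_width
            )
        for (r, c), rad in zip(self.centers, self.radii):
            mask |= _ring_mask((h, w), (r, c), rad + 1.5, self.soma_ring_width)
        return mask

    def calcein_mask(self, viability_floor: float = 0.2) -> np.ndarray:
        """Union of calcein-positive (vital) areas.

        Calcein-AM fluoresces only in live cells, so cells at or below the
        floor contribute nothing; the labelled area of a partially viable
        cell shrinks with viability (radius ~ sqrt(v), area ~ v), as dying
        cells round up and lose dye-retaining cytoplasm.
        """
        h, w, _ = self.shape
        mask = np.zeros((h, w), dtype=bool)
        for (r, c), rad, v in zip(self.centers, self.radii, self.viability):
            if v > viability_floor:
                mask |= _disk_mask((h, w), (r, c), rad * self.calcein_scale * np.sqrt(v))
        return mask

    def body_geometry(self) -> tuple[np.ndarray, float] | None:
        """Center and radius of the organoid body enclosing all cells."""
        if self.n_cells == 0:
            return None
        centroid = self.centers.mean(axis=0)
        reach = np.linalg.norm(self.centers - centroid, axis=1)
        radius = float((reach + self.radii * self.calcein_scale).max() + 10.0)
        return centroid, radius


@dataclass
class CalciumTruth:
    """Planted calcium-transient structure for a field of cells.

    event_times[i] holds the transient onset times (s) of cell i;
    non-participating cells have empty arrays.  Connected cells (adjacency)
    were assigned shared component event times up to per-cell jitter.
    """

    event_times: list[np.ndarray]
    participating: np.ndarray
    frame_interval: float = 1.52  # s per frame
    duration: float = 600.0  # s (10-minute window)
    decay: float = 8.0  # s, exponential decay constant
    amplitude: float = 0.8  # ΔF/F0 units
    noise_sd: float = 0.05  # ΔF/F0 units
    baseline: float = 100.0  # raw fluorescence baseline
    jitter_frames: float = 1.0
    adjacency: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")
        if self.duration < self.frame_interval:
            raise ValueError("duration shorter than one frame")
        self.participating = np.asarray(self.participating, dtype=bool)
        for i, t in enumerate(self.event_times):
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError("event times must lie in [0, duration]")
            if not self.participating[i] and t.size:
                raise ValueError("non-participating cell has events")
            self.event_times[i] = t

    @property
    def n_cells(self) -> int:
        return len(self.event_times)


@dataclass
class ExpressionTruth:
    """Planted pathway shifts and their links to drug sensitivity.

    pathway_effects maps pathway -> per-sample effect (log-scale expression
    shift applied to member genes).  drug_links maps drug -> {pathway: coef};
    a drug's response score shifts by coef * effect in each sample.
    """

    genes: list[str]
    samples: list[str]
    pathway_effects: dict[str, np.ndarray]
    drug_links: dict[str, dict[str, float]]
    response_noise_sd: float = 0.3
    expr_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.samples)
        for p, e in self.pathway_effects.items():
            e = np.asarray(e, dtype=float)
            if e.shape != (n,):
                raise ValueError(f"effect vector for {p!r} has wrong length")
            if not np.isfinite(e).all():
                raise ValueError(f"non-finite effect for {p!r}")
            self.pathway_effects[p] = e


# --------------------------------------------------------------------------
# Dose-response screen
# --------------------------------------------------------------------------

def four_pl(c, top: float, bottom: float, ic50: float, hill: float):
    """Four-parameter logistic viability v(c) = bottom + (top-bottom)/(1+(c/ic50)^hill)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def make_dilution_series(top_conc: float, fold: float, n_points: int) -> np.ndarray:
    """Descending geometric dilution series: k-th value = top_conc / fold**k."""
    if not (np.isfinite(top_conc) and top_conc > 0):
        raise ValueError("top_conc must be positive and finite")
    if not (np.isfinite(fold) and fold > 1):
        raise ValueError("fold must be > 1 and finite")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    return top_conc / fold ** np.arange(n_points, dtype=float)


def _well_names() -> list[str]:
    return [f"{r}{c}" for r in PLATE_ROWS for c in range(1, PLATE_COLS + 1)]


def make_plate_layout(
    n_drugs: int,
    series: np.ndarray,
    n_replicates: int,
    n_vehicle: int = 8,
    positive_control: bool = True,
    drug_ids: list[str] | None = None,
    allow_multi_plate: bool = True,
) -> pd.DataFrame:
    """Lay a screen out on 384-well plates.

    Each drug occupies a full dilution series x replicates block, kept whole
    on a single plate.  Every plate carries ``n_vehicle`` DMSO vehicle wells
    (normalization/QC is per-plate); the positive-control series (duplicate
    of the drug series, drug_id 'bortezomib') sits on the first plate.
    Screens too large for one plate are split across plates; a screen whose
    single-drug block cannot fit raises.

    Returns a tidy frame with columns plate_id, well, role, drug_id,
    concentration_M, replicate.
    """
    series = np.asarray(series, dtype=float)
    if (series <= 0).any():
        raise ValueError("concentrations must be positive")
    if n_replicates < 1 or n_drugs < 0:
        raise ValueError("n_drugs >= 0 and n_replicates >= 1 required")
    block = len(series) * n_replicates
    if block + n_vehicle > PLATE_WELLS:
        raise ValueError(
            f"a single drug series ({block} wells) plus {n_vehicle} vehicle wells "
            f"exceeds one {PLATE_WELLS}-well plate"
        )
    if drug_ids is None:
        drug_ids = [f"drug_{i + 1:02d}" for i in range(n_drugs)]
    if len(drug_ids) != n_drugs:
        raise ValueError("drug_ids length must equal n_drugs")

    units: list[tuple[str, str]] = []
    if positive_control:
        units.append((POSITIVE_CONTROL_ID, "positive_control"))
    units.extend((d, "drug") for d in drug_ids)

    total_drug_wells = len(units) * block
    n_plates_needed = int(np.ceil(total_drug_wells / (PLATE_WELLS - n_vehicle)))
    if n_plates_needed > 1 and not allow_multi_plate:
        raise ValueError(
            f"{total_drug_wells} drug wells exceed one plate "
            f"({PLATE_WELLS - n_vehicle} usable); multi-plate layout required"
        )

    rows: list[dict] = []
    names = _well_names()
    plate = 1
    cursor = 0

    def plate_id(p: int) -> str:
        return f"P{p}"

    def start_plate(p: int) -> int:
        for v in range(n_vehicle):
            rows.append(
                {
                    "plate_id": plate_id(p),
                    "well": names[v],
                    "role": "vehicle",
                    "drug_id": "DMSO",
                    "concentration_M": np.nan,
                    "replicate": v + 1,
                }
            )
        return n_vehicle

    cursor = start_plate(plate)
    for drug, role in units:
        if cursor + block > PLATE_WELLS:
            plate += 1
            cursor = start_plate(plate)
        for rep in range(1, n_replicates + 1):
            for conc in series:
                rows.append(
                    {
                        "plate_id": plate_id(plate),
                        "well": names[cursor],
                        "role": role,
                        "drug_id": drug,
                        "concentration_M": conc,
                        "replicate": rep,
                    }
                )
                cursor += 1
    layout = pd.DataFrame(rows)
    dup = layout.duplicated(subset=["plate_id", "well"])
    assert not dup.any(), "internal error: duplicate well addresses"
    return layout


def make_screen_truth(
    n_drugs: int = 41,
    hit_drugs: dict[str, DrugTruth] | None = None,
    sigma: float = 0.05,
    seed: int = 0,
    drug_ids: list[str] | None = None,
) -> ScreenTruth:
    """Default screen truth: inactive (flat) drugs except explicitly planted hits.

    The bortezomib-like positive control is always potent (ic50 1e-7 M,
    bottom 0.02), matching its role of killing organoids at high dose.
    """
    if drug_ids is None:
        drug_ids = [f"drug_{i + 1:02d}" for i in range(n_drugs)]
    drugs = {d: DrugTruth(top=1.0, bottom=1.0) for d in drug_ids}
    hits = set()
    if hit_drugs:
        for d, t in hit_drugs.items():
            if d not in drugs:
                raise ValueError(f"hit drug {d!r} not in screen")
            drugs[d] = t
            hits.add(d)
    drugs[POSITIVE_CONTROL_ID] = DrugTruth(top=1.0, bottom=0.02, ic50=1e-7, hill=1.2)
    return ScreenTruth(drugs=drugs, hits=frozenset(hits), sigma=sigma, seed=seed)


def simulate_viability(
    layout: pd.DataFrame, truth: ScreenTruth, seed: int | None = None
) -> pd.DataFrame:
    """Raw per-well readouts (fluorescence-area surrogate) for a layout.

    Vehicle wells scatter around a per-plate baseline; drug wells are
    baseline * v(c) * lognormal noise with v the drug's latent 4PL curve.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    drug_rows = layout[layout["role"].isin(["drug", "positive_control"])]
    missing = set(drug_rows["drug_id"]) - set(truth.drugs)
    if missing:
        raise KeyError(f"no truth parameters for drugs: {sorted(missing)}")

    plates = list(dict.fromkeys(layout["plate_id"]))
    plate_base = {
        p: truth.baseline * np.exp(rng.normal(0.0, truth.plate_sigma)) for p in plates
    }
    readouts = np.empty(len(layout), dtype=float)
    for idx, row in enumerate(layout.itertuples(index=False)):
        base = plate_base[row.plate_id]
        if row.role == "vehicle":
            v = 1.0
        elif row.role in ("drug", "positive_control"):
            t = truth.drugs[row.drug_id]
            v = float(four_pl(row.concentration_M, t.top, t.bottom, t.ic50, t.hill))
        else:  # empty
            readouts[idx] = 0.0
            continue
        noise = np.exp(rng.normal(0.0, truth.sigma)) if truth.sigma > 0 else 1.0
        readouts[idx] = base * v * noise
    out = layout[["plate_id", "well"]].copy()
    out["readout"] = readouts
    return out


# --------------------------------------------------------------------------
# Organoid image phantoms
# --------------------------------------------------------------------------

def _disk_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    return d2 <= radius**2


def _ring_mask(shape, center, radius, width) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return np.abs(d - radius) <= width / 2.0


def _segment_distance(shape, p0, p1) -> np.ndarray:
    """Per-pixel distance to the line segment p0-p1."""
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    p = np.stack([rr, cc], axis=-1).astype(float)
    a = np.asarray(p0, dtype=float)
    b = np.asarray(p1, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0:
        return np.linalg.norm(p - a, axis=-1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(p - proj, axis=-1)


def _segment_mask(shape, p0, p1, width) -> np.ndarray:
    return _segment_distance(shape, p0, p1) <= width / 2.0


def make_image_truth(
    n_cells: int = 10,
    shape: tuple[int, int, int] = (512, 512, 5),
    radius_range: tuple[float, float] = (6.0, 9.0),
    connect_fraction: float = 0.7,
    viability_range: tuple[float, float] = (0.7, 1.0),
    seed: int = 0,
) -> ImageTruth:
    """Random organoid phantom: separated cells, nearest-neighbour filaments.

    Cells are placed with rejection sampling so nuclei do not touch; a
    fraction of cells is wired to its nearest placed neighbour, forming the
    tumor-microtube network.
    """
    rng = np.random.default_rng(seed)
    h, w, _ = shape
    # cells cluster inside a central organoid region, not the whole frame
    field_center = np.array([h / 2.0, w / 2.0])
    field_radius = 0.3 * min(h, w)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    attempts = 0
    while len(centers) < n_cells and attempts < 20000:
        attempts += 1
        u = rng.uniform(0.0, 1.0)
        theta = rng.uniform(0.0, 2.0 * np.pi)
        c = field_center + field_radius * np.sqrt(u) * np.array(
            [np.cos(theta), np.sin(theta)]
        )
        r = rng.uniform(*radius_range)
        if all(
            np.linalg.norm(c - c2) > 3.5 * (r + r2) for c2, r2 in zip(centers, radii)
        ):
            centers.append(c)
            radii.append(r)
    if len(centers) < n_cells:
        raise ValueError("image too small for requested cell count/radii")
    centers_arr = np.array(centers) if centers else np.zeros((0, 2))
    adjacency: list[tuple[int, int]] = []
    if n_cells >= 2:
        n_connected = max(2, int(round(connect_fraction * n_cells)))
        chosen = rng.choice(n_cells, size=n_connected, replace=False)
        for i in chosen:
            d = np.linalg.norm(centers_arr - centers_arr[i], axis=1)
            d[i] = np.inf
            j = int(np.argmin(d))
            if i != j:
                adjacency.append((int(i), j))
    viability = rng.uniform(*viability_range, size=n_cells)
    return ImageTruth(
        centers=centers_arr,
        radii=np.array(radii),
        adjacency=adjacency,
        viability=viability,
        shape=shape,
    )


def _soft_disk(shape, center, radius, edge=1.0) -> np.ndarray:
    """Disk with a linear intensity roll-off of width ``edge`` at the rim."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return np.clip((radius + edge / 2.0 - d) / edge, 0.0, 1.0)


def _soft_segment(shape, p0, p1, width, edge=1.0) -> np.ndarray:
    d = _segment_distance(shape, p0, p1)
    return np.clip((width / 2.0 + edge / 2.0 - d) / edge, 0.0, 1.0)


def _soft_ring(shape, center, radius, width, edge=1.0) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    return np.clip((width / 2.0 + edge / 2.0 - np.abs(d - radius)) / edge, 0.0, 1.0)


def render_organoid_images(
    truth: ImageTruth,
    seed: int = 0,
    nuclei_amp: float = 20000.0,
    nestin_amp: float = 16000.0,
    calcein_amp: float = 24000.0,
    body_amp: float = 60.0,
    background: float = 200.0,
    read_noise_sd: float = 30.0,
    viability_floor: float = 0.2,
) -> OrganoidImageSet:
    """Render a phantom into 16-bit nuclei/nestin/calcein z-stacks.

    Structures are drawn on a 2-D plane with ~1 px anti-aliased edges, then
    distributed over z with a bell profile so the maximum intensity
    projection recovers the plane; additive Gaussian read noise and clipping
    to the 16-bit range follow.  The calcein channel carries a faint
    organoid-body glow (the footprint of the whole spheroid) on top of
    bright disks for live cells; cells at or below ``viability_floor`` are
    dark, as calcein-AM only fluoresces in viable cells.
    """
    h, w, z = truth.shape
    if len(truth.radii) and 2 * truth.radii.max() * truth.calcein_scale > min(h, w):
        raise ValueError("image too small for requested radii")
    rng = np.random.default_rng(seed)
    planes = {ch: np.zeros((h, w), dtype=float) for ch in ("nuclei", "nestin", "calcein")}

    body = truth.body_geometry()
    if body is not None:
        planes["calcein"] += body_amp * _soft_disk((h, w), body[0], body[1], edge=5.0)
    for (r, c), rad, v in zip(truth.centers, truth.radii, truth.viability):
        planes["nuclei"] += nuclei_amp * _soft_disk((h, w), (r, c), rad)
        planes["nestin"] += nestin_amp * _soft_ring(
            (h, w), (r, c), rad + 1.5, truth.soma_ring_width
        )
        if v > viability_floor:
            planes["calcein"] += calcein_amp * v * _soft_disk(
                (h, w), (r, c), rad * truth.calcein_scale * np.sqrt(v)
            )
    for i, j in truth.adjacency:
        planes["nestin"] = np.maximum(
            planes["nestin"],
            nestin_amp
            * _soft_segment((h, w), truth.centers[i], truth.centers[j], truth.filament_width),
        )

    z_profile = np.exp(-0.5 * ((np.arange(z) - (z - 1) / 2.0) / max(z / 4.0, 1.0)) ** 2)
    z_profile /= z_profile.max()
    channels = {}
    for ch, plane in planes.items():
        stack = background + plane[None, :, :] * z_profile[:, None, None]
        stack = stack + rng.normal(0.0, read_noise_sd, size=stack.shape)
        channels[ch] = np.clip(stack, 0, 65535).astype(np.uint16)
    return OrganoidImageSet(channels=channels)


# --------------------------------------------------------------------------
# Calcium traces
# --------------------------------------------------------------------------

def _component_labels(n_cells: int, adjacency: list[tuple[int, int]]) -> np.ndarray:
    """Connected components of the cell network (union-find)."""
    parent = list(range(n_cells))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in adjacency:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return np.array([find(i) for i in range(n_cells)])


def make_calcium_truth(
    n_cells: int = 12,
    adjacency: list[tuple[int, int]] | None = None,
    rate_per_min: float = 1.0,
    participating_fraction: float = 0.8,
    duration: float = 600.0,
    frame_interval: float = 1.52,
    amplitude: float = 0.8,
    noise_sd: float = 0.05,
    min_separation: float = 15.0,
    jitter_frames: float = 1.0,
    seed: int = 0,
) -> CalciumTruth:
    """Plant transients shared within network components (homogeneous Poisson).

    Each connected component draws one Poisson event train (rate per cell
    per minute, thinned to ``min_separation`` seconds between events); every
    participating member inherits those times.  Cells flagged
    non-participating get no events.
    """
    rng = np.random.default_rng(seed)
    if adjacency is None:
        # default: chain half the cells into one network component
        k = n_cells // 2
        adjacency = [(i, i + 1) for i in range(max(k - 1, 0))]
    comp = _component_labels(n_cells, adjacency)
    participating = rng.random(n_cells) < participating_fraction
    # cells wired into the network always participate
    for i, j in adjacency:
        participating[i] = participating[j] = True

    comp_events: dict[int, np.ndarray] = {}
    for label in np.unique(comp):
        n_events = rng.poisson(rate_per_min * duration / 60.0)
        times = np.sort(rng.uniform(0.0, duration, size=n_events))
        kept: list[float] = []
        for t in times:
            if not kept or t - kept[-1] >= min_separation:
                kept.append(float(t))
        comp_events[int(label)] = np.array(kept)

    event_times: list[np.ndarray] = []
    for i in range(n_cells):
        if not participating[i]:
            event_times.append(np.array([]))
            continue
        base = comp_events[int(comp[i])]
        jitter = rng.normal(0.0, jitter_frames * frame_interval, size=base.size)
        event_times.append(np.clip(base + jitter, 0.0, duration))
    return CalciumTruth(
        event_times=event_times,
        participating=participating,
        frame_interval=frame_interval,
        duration=duration,
        amplitude=amplitude,
        noise_sd=noise_sd,
        jitter_frames=jitter_frames,
        adjacency=sorted({tuple(sorted(p)) for p in adjacency}),
    )


def simulate_calcium_traces(truth: CalciumTruth, seed: int = 0) -> pd.DataFrame:
    """Raw fluorescence traces sampled on the frame grid.

    trace = baseline * (1 + Σ transients) + Gaussian read noise, where each
    transient rises instantly at its event time and decays exponentially.
    Returns a tidy frame: time_s plus one cell_<i> column per cell.
    """
    rng = np.random.default_rng(seed)
    n_frames = int(np.floor(truth.duration / truth.frame_interval))
    if n_frames < 1:
        raise ValueError("duration shorter than one frame")
    t = np.arange(n_frames) * truth.frame_interval
    data = {"time_s": t}
    for i, events in enumerate(truth.event_times):
        signal = np.zeros(n_frames)
        for e in events:
            after = t >= e
            signal[after] += truth.amplitude * np.exp(-(t[after] - e) / truth.decay)
        raw = truth.baseline * (1.0 + signal)
        if truth.noise_sd > 0:
            raw = raw + rng.normal(0.0, truth.noise_sd * truth.baseline, size=n_frames)
        data[f"cell_{i}"] = raw
    return pd.DataFrame(data)


# --------------------------------------------------------------------------
# Expression matrices with planted pathway-response structure
# --------------------------------------------------------------------------

def make_expression_truth(
    gene_sets: dict[str, list[str]],
    n_samples: int = 20,
    neg_pathways: list[str] | None = None,
    pos_pathways: list[str] | None = None,
    mixed_pathways: list[str] | None = None,
    drug_ids: list[str] | None = None,
    effect_size: float = 1.0,
    seed: int = 0,
) -> ExpressionTruth:
    """Plant the three qualitative pathway-response blocks seen in tumors.

    A latent per-sample sensitivity factor u drives every drug's response
    score.  Pathways in the positive block share +u (enrichment tracks
    response), the negative block shares -u, and the mixed block follows an
    orthogonal latent factor v, producing near-zero, sign-divergent
    correlations.  Member genes of each planted pathway are shifted by the
    sample's effect on the log-expression scale.
    """
    rng = np.random.default_rng(seed)
    neg_pathways = neg_pathways or []
    pos_pathways = pos_pathways or []
    mixed_pathways = mixed_pathways or []
    planted = neg_pathways + pos_pathways + mixed_pathways
    missing = [p for p in planted if p not in gene_sets]
    if missing:
        raise KeyError(f"planted pathways not in the gene-set collection: {missing}")

    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    u = rng.normal(0.0, 1.0, size=n_samples)
    v = rng.normal(0.0, 1.0, size=n_samples)

    effects: dict[str, np.ndarray] = {}
    for p in neg_pathways:
        effects[p] = effect_size * (-u + 0.3 * rng.normal(size=n_samples))
    for p in pos_pathways:
        effects[p] = effect_size * (u + 0.3 * rng.normal(size=n_samples))
    for p in mixed_pathways:
        effects[p] = effect_size * (v + 0.3 * rng.normal(size=n_samples))

    if drug_ids is None:
        drug_ids = [f"drug_{i + 1:02d}" for i in range(8)]
    anchor = pos_pathways[0] if pos_pathways else (planted[0] if planted else None)
    links: dict[str, dict[str, float]] = {}
    for d in drug_ids:
        links[d] = {anchor: 1.0} if anchor else {}

    genes = sorted({g for gs in gene_sets.values() for g in gs})
    return ExpressionTruth(
        genes=genes,
        samples=samples,
        pathway_effects=effects,
        drug_links=links,
        seed=seed,
    )


def simulate_expression(
    truth: ExpressionTruth,
    gene_sets: dict[str, list[str]],
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples) + drug response scores (drugs x samples).

    Member genes of each planted pathway are shifted by the sample's effect
    size on top of i.i.d. Gaussian log-expression; the response score of
    each linked drug shifts proportionally to the linked pathway's effect
    with its stated sign, plus noise.
    """
    for p in truth.pathway_effects:
        if p not in gene_sets:
            raise KeyError(f"planted pathway {p!r} not found in the collection")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    genes = truth.genes
    samples = truth.samples
    base = rng.normal(7.0, 1.0, size=len(genes))
    expr = base[:, None] + rng.normal(
        0.0, truth.expr_noise_sd, size=(len(genes), len(samples))
    )
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    gene_index = {g: i for i, g in enumerate(genes)}
    for p, eff in truth.pathway_effects.items():
        members = [gene_index[g] for g in gene_sets[p] if g in gene_index]
        expr_df.iloc[members, :] += eff[None, :]

    resp = {}
    for d, linkmap in truth.drug_links.items():
        score = rng.normal(0.0, truth.response_noise_sd, size=len(samples))
        for p, coef in linkmap.items():
            score = score + coef * truth.pathway_effects[p]
        resp[d] = score
    resp_df = pd.DataFrame(resp, index=samples).T
    resp_df.index.name = "drug_id"
    return expr_df, resp_df
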