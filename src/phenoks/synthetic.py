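"""Synthetic compound-screen generator with known ground truth.

Emulates a 96-well high-content screen of an EGFR-pathway inhibitor panel:
14 compounds plus a DMSO control, five post-stimulation time points
(0/5/30/60/180 min), several hundred cells per condition and two
independent replicate experiments. Compounds belong to *mechanism
archetypes* — shared vectors of per-descriptor effect sizes (location
shift in control-SD units, scale factor) — so the true mechanism grouping
is known and downstream clustering can be scored against it.

Two output modes:

* feature-table mode (default): per-cell descriptor values drawn directly
  from the generative model (log-normal intensities, Poisson counts);
* image mode: multi-channel 2-D fields (DNA / EGFR-like / two markers)
  with ground-truth masks and spot coordinates, for exercising the
  segmentation and feature-extraction stages.

Everything is a pure function of the configuration and its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "MechanismArchetype",
    "SyntheticPanelConfig",
    "SyntheticCellImage",
    "SyntheticPanel",
    "default_archetypes",
    "default_descriptor_kinds",
    "generate_panel",
    "generate_batch_features",
    "render_cell_image",
]

# Anchor minutes for all piecewise-linear time schedules.
_ANCHOR_T = np.array([0.0, 5.0, 30.0, 60.0, 180.0])

# How strongly archetype effects are expressed over time after EGF
# stimulation (compounds are pre-incubated, so t=0 is not fully silent).
_EFFECT_WEIGHT = np.array([0.2, 0.6, 1.0, 0.9, 0.7])

# Control-cell kinetics of stimulation-responsive descriptors, as
# multipliers of the descriptor's baseline mean. The EGFR-like marker
# accumulates perinuclearly to a maximum at 30 min and is then degraded;
# pERK translocates to the nucleus (peak 30 min) and pAkt to the PM
# (peak 5 min).
_CONTROL_KINETICS = {
    "ratio_perinuclear_PM_EGFR": [1.0, 1.5, 2.2, 1.7, 1.2],
    "perinuclear_EGFR_integrated": [1.0, 1.4, 2.0, 1.6, 1.1],
    "PM_EGFR_integrated": [1.0, 0.85, 0.7, 0.75, 0.8],
    "cell_EGFR_integrated": [1.0, 1.0, 0.95, 0.8, 0.55],
    "cytoplasm_EGFR_integrated": [1.0, 1.0, 0.95, 0.8, 0.55],
    "nucleus_pERK_integrated": [0.4, 0.8, 1.0, 0.7, 0.5],
    "PM_pAkt_integrated": [0.5, 1.0, 0.8, 0.6, 0.5],
}

_CHANNELS = ("EGFR", "Tfn", "pERK", "pAkt")
_REGIONS = ("nucleus", "cell", "cytoplasm", "perinuclear", "PM")

# Per-cell coefficient of variation of log-normal intensity descriptors.
DEFAULT_CV = 0.3


def default_descriptor_kinds() -> dict:
    """Default feature-table descriptor catalogue: name -> generator kind.

    Intensity descriptors (log-normal, kind "intensity") cross the five
    regions with the four channels; count descriptors (Poisson, kind
    "count") cover endosome and colocalization counts; ratio descriptors
    are log-normal around the trafficking schedule.
    """
    kinds = {}
    for ch in _CHANNELS:
        for region in _REGIONS:
            kinds[f"{region}_{ch}_integrated"] = "intensity"
    for ch in ("EGFR", "Tfn"):
        for region in ("perinuclear", "PM", "cytoplasm"):
            kinds[f"{region}_{ch}_endosome_count"] = "count"
        kinds[f"ratio_perinuclear_PM_{ch}"] = "intensity"
    for region in ("perinuclear", "PM"):
        kinds[f"{region}_endosome_EGFR_Tfn_coloc_count"] = "count"
    return kinds


@dataclass(frozen=True)
class MechanismArchetype:
    """One simulated mechanism class.

    ``effects`` maps descriptor name -> (location shift in control-SD
    units, scale factor). The shift moves the treated per-cell mean by
    that many control standard deviations; the scale factor multiplies the
    within-population spread. Effects are modulated over time by the
    shared post-stimulation weight schedule. The null archetype has shift
    0 and scale 1 everywhere (an empty mapping).
    """

    name: str
    effects: dict = field(default_factory=dict)

    def effect(self, descriptor: str, time_min: float) -> tuple:
        shift, scale = self.effects.get(descriptor, (0.0, 1.0))
        w = float(np.interp(time_min, _ANCHOR_T, _EFFECT_WEIGHT))
        return shift * w, 1.0 + (scale - 1.0) * w


def default_archetypes() -> list:
    """The four default mechanism archetypes.

    null_like — essentially inactive compounds; akt_axis — blocks Akt
    phosphorylation (PM pAkt down) with compensatory ERK activation;
    receptor_block — kinase-dead receptor: both pathways down, ligand
    uptake reduced; trafficking_block — receptor stuck at the PM,
    recycling-marker retention, reduced perinuclear accumulation.
    """
    return [
        MechanismArchetype("null_like", {}),
        MechanismArchetype("akt_axis", {
            "PM_pAkt_integrated": (-2.2, 1.15),
            "cytoplasm_pAkt_integrated": (-1.8, 1.0),
            "perinuclear_pAkt_integrated": (-1.4, 1.0),
            "nucleus_pERK_integrated": (+1.5, 1.0),
            "cell_pERK_integrated": (+1.0, 1.0),
        }),
        MechanismArchetype("receptor_block", {
            "nucleus_pERK_integrated": (-2.2, 0.9),
            "cell_pERK_integrated": (-1.6, 0.9),
            "PM_pAkt_integrated": (-2.0, 0.9),
            "cytoplasm_pAkt_integrated": (-1.5, 1.0),
            "perinuclear_EGFR_integrated": (-1.8, 1.0),
            "ratio_perinuclear_PM_EGFR": (-1.6, 1.0),
            "perinuclear_EGFR_endosome_count": (-1.4, 1.0),
        }),
        MechanismArchetype("trafficking_block", {
            "ratio_perinuclear_PM_EGFR": (-1.8, 1.0),
            "perinuclear_EGFR_integrated": (-1.4, 1.0),
            "PM_EGFR_integrated": (+1.8, 1.1),
            "PM_Tfn_integrated": (+2.2, 1.0),
            "PM_Tfn_endosome_count": (+1.8, 1.0),
            "PM_endosome_EGFR_Tfn_coloc_count": (+1.5, 1.0),
            "perinuclear_EGFR_endosome_count": (-1.0, 1.0),
        }),
    ]


@dataclass(frozen=True)
class SyntheticPanelConfig:
    """Study-design parameters of the synthetic screen."""

    n_compounds: int = 14
    include_control: bool = True
    time_points_min: tuple = (0, 5, 30, 60, 180)
    n_cells_per_condition: int = 600
    n_replicates: int = 2
    mechanism_groups: tuple | None = None   # defaults to default_archetypes()
    image_mode: bool = False
    rng_seed: int = 0
    cv: float = DEFAULT_CV
    cells_per_image: int = 8                # image mode only
    image_shape: tuple = (256, 256)

    def archetypes(self) -> list:
        if self.mechanism_groups is None:
            return default_archetypes()
        return list(self.mechanism_groups)

    def validate(self) -> None:
        if self.n_cells_per_condition < 50:
            raise ValueError("n_cells_per_condition must be >= 50")
        tp = list(self.time_points_min)
        if not tp:
            raise ValueError("time_points_min must not be empty")
        if tp[0] != 0 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("time_points_min must be strictly increasing "
                             "and include 0")
        if self.n_replicates < 1 or self.n_compounds < 1:
            raise ValueError("n_compounds and n_replicates must be >= 1")
        known = set(default_descriptor_kinds())
        for arch in self.archetypes():
            unknown = set(arch.effects) - known
            if unknown:
                raise ValueError(
                    f"mechanism_groups: archetype {arch.name!r} references "
                    f"unknown descriptors {sorted(unknown)}")


@dataclass
class SyntheticCellImage:
    """One rendered multi-channel field with exact ground truth."""

    channels: dict                 # channel name -> 2-D float array
    nucleus_labels: np.ndarray
    cell_labels: np.ndarray
    spot_coords: dict              # channel -> list per cell of (r, c) arrays
    spot_counts: dict              # channel -> list of ints per cell

    def n_cells(self) -> int:
        return int(self.cell_labels.max())


@dataclass
class SyntheticPanel:
    """Output of :func:`generate_panel`."""

    config: SyntheticPanelConfig
    plate_map: pd.DataFrame        # batch_id, compound, time_min, replicate, well
    features: pd.DataFrame | None  # long per-cell table (feature-table mode)
    ground_truth: dict             # compound -> archetype name
    images: dict | None = None     # batch_id -> list of SyntheticCellImage

    @property
    def compounds(self) -> list:
        return sorted(c for c in self.ground_truth if c != "DMSO")


def _compound_assignments(config: SyntheticPanelConfig):
    """Deterministic compound -> (archetype, potency) map.

    Compounds are dealt round-robin-by-block across archetypes; potencies
    spread 0.85-1.15 within a group so same-mechanism compounds are
    similar but not identical.
    """
    archs = config.archetypes()
    names = [f"cmpd{i + 1:02d}" for i in range(config.n_compounds)]
    # block sizes as even as possible, e.g. 14 over 4 groups -> 4,4,3,3
    sizes = np.full(len(archs), config.n_compounds // len(archs))
    sizes[: config.n_compounds % len(archs)] += 1
    out = {}
    idx = 0
    for arch, size in zip(archs, sizes):
        for j in range(size):
            pot = 1.0 if size == 1 else 0.85 + 0.3 * j / (size - 1)
            out[names[idx]] = (arch, pot)
            idx += 1
    return out


def _baseline(descriptor: str, kind: str, index: int):
    """Deterministic per-descriptor baseline (mean or Poisson rate)."""
    if kind == "count":
        return 3.0 + 2.0 * (index % 4)          # lambda in 3..9
    if descriptor.startswith("ratio_"):
        return 1.2
    return 60.0 * (1.0 + (index % 7))           # arbitrary fluorescence units


def _kinetics(descriptor: str, time_min: float) -> float:
    sched = _CONTROL_KINETICS.get(descriptor)
    if sched is None:
        return 1.0
    return float(np.interp(time_min, _ANCHOR_T, sched))


def generate_batch_features(
    compound: str,
    archetype: MechanismArchetype,
    potency: float,
    time_min: float,
    n_cells: int,
    rng: np.random.Generator,
    cv: float = DEFAULT_CV,
    descriptor_kinds: dict | None = None,
) -> pd.DataFrame:
    """Per-cell descriptor values for one (compound, time) batch.

    Intensity descriptors are log-normal with unit-mean multiplicative
    noise: ``value = m * f * exp(s*eps - s^2/2)`` with
    ``s = scale * sqrt(ln(1 + cv^2))``, so the control mean is exactly the
    baseline ``m`` and the control SD exactly ``m * cv``. A location shift
    of ``d`` control-SD units enters as the factor ``f = 1 + d*cv``
    (floored at 0.05), which moves the mean by exactly ``d`` control SDs
    while keeping values positive. Count descriptors are Poisson with rate
    shifted by ``d * sqrt(rate)`` (scale factors do not apply to counts).
    """
    kinds = descriptor_kinds or default_descriptor_kinds()
    data = {}
    for i, (name, kind) in enumerate(kinds.items()):
        shift, scale = archetype.effect(name, time_min)
        shift *= potency
        if kind == "count":
            lam = _baseline(name, kind, i) * _kinetics(name, time_min)
            lam = max(lam + shift * np.sqrt(lam), 0.05)
            data[name] = rng.poisson(lam, size=n_cells).astype(float)
        else:
            m = _baseline(name, kind, i) * _kinetics(name, time_min)
            f = max(1.0 + shift * cv, 0.05)
            s = scale * np.sqrt(np.log1p(cv * cv))
            eps = rng.standard_normal(n_cells)
            data[name] = m * f * np.exp(s * eps - 0.5 * s * s)
    out = pd.DataFrame(data)
    out.insert(0, "cell", np.arange(1, n_cells + 1))
    return out


def _well_name(index: int) -> str:
    return f"{chr(ord('A') + (index // 12) % 8)}{index % 12 + 1:02d}"


def generate_panel(config: SyntheticPanelConfig) -> SyntheticPanel:
    """Generate the full synthetic screen.

    One batch per (compound, time, replicate) plus the DMSO control
    batches (the control is the null archetype: every effect zero).
    Batch-level randomness is drawn from independent streams seeded by
    (rng_seed, batch index), so output is reproducible bit-for-bit and
    independent of iteration order.
    """
    config.validate()
    assignments = _compound_assignments(config)
    null_arch = MechanismArchetype("null", {})
    samples = list(assignments.items())
    if config.include_control:
        samples.append(("DMSO", (null_arch, 1.0)))

    rows = []
    feature_frames = []
    images = {} if config.image_mode else None
    batch_index = 0
    for rep in range(1, config.n_replicates + 1):
        for s_idx, (compound, (arch, pot)) in enumerate(samples):
            for t_idx, t in enumerate(config.time_points_min):
                batch_id = f"r{rep}_{compound}_t{int(t):03d}"
                well = _well_name(s_idx * len(config.time_points_min) + t_idx)
                rows.append({
                    "batch_id": batch_id, "compound": compound,
                    "time_min": t, "replicate": rep, "well": well,
                })
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        entropy=config.rng_seed, spawn_key=(batch_index,))
                )
                batch_index += 1
                if config.image_mode:
                    images[batch_id] = _render_batch_images(
                        config, arch, pot, t, rng)
                else:
                    feats = generate_batch_features(
                        compound, arch, pot, t, config.n_cells_per_condition,
                        rng, cv=config.cv)
                    feats.insert(0, "batch_id", batch_id)
                    feats.insert(1, "compound", compound)
                    feats.insert(2, "time_min", t)
                    feats.insert(3, "replicate", rep)
                    feature_frames.append(feats)

    plate_map = pd.DataFrame(rows)
    features = (pd.concat(feature_frames, ignore_index=True)
                if feature_frames else None)
    ground_truth = {c: a.name for c, (a, _) in assignments.items()}
    if config.include_control:
        ground_truth["DMSO"] = "null_like" if any(
            a.name == "null_like" for a in config.archetypes()) else "null"
    return SyntheticPanel(config=config, plate_map=plate_map,
                          features=features, ground_truth=ground_truth,
                          images=images)


# ---------------------------------------------------------------------------
# image mode


def render_cell_image(
    n_cells: int,
    spot_counts,
    shape: tuple = (256, 256),
    cell_radius: float = 26.0,
    nucleus_radius: float = 9.0,
    seed: int | None = 0,
    background: float = 4.0,
    noise_sd: float = 0.0,
    spot_sigma: float = 2.0,
    perinuclear_fraction: float = 0.5,
    max_retries: int = 200,
) -> SyntheticCellImage:
    """Render one synthetic multi-channel field.

    Cells are deformed (randomly oriented, eccentric) ellipses with
    concentric elliptical nuclei; endosome spots are Gaussian blobs
    (``spot_sigma`` px) placed inside the owning cell, split between a
    perinuclear shell and the cell periphery by ``perinuclear_fraction``.
    Ground-truth masks are guaranteed disjoint (placement retried up to
    ``max_retries`` times, then a generation error is raised) and the
    returned spot coordinates/counts exactly match the rendered content.
    """
    rng = np.random.default_rng(seed)
    spot_counts = list(spot_counts)
    if len(spot_counts) != n_cells:
        raise ValueError("spot_counts must have one entry per cell")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    centers = []
    for k in range(1, n_cells + 1):
        placed = False
        for _ in range(max_retries):
            cy = rng.uniform(cell_radius + 2, h - cell_radius - 2)
            cx = rng.uniform(cell_radius + 2, w - cell_radius - 2)
            theta = rng.uniform(0, np.pi)
            a = cell_radius * rng.uniform(0.85, 1.1)
            b = cell_radius * rng.uniform(0.6, 0.85)
            ct, st = np.cos(theta), np.sin(theta)
            u = (xx - cx) * ct + (yy - cy) * st
            v = -(xx - cx) * st + (yy - cy) * ct
            cell_mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            if not (cell_mask & occupied).any():
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {k} without overlap after "
                f"{max_retries} retries")
        na = nucleus_radius * (a / cell_radius)
        nb = nucleus_radius * (b / cell_radius)
        nucleus_mask = (u / na) ** 2 + (v / nb) ** 2 <= 1.0
        occupied |= cell_mask
        cell_labels[cell_mask] = k
        nucleus_labels[nucleus_mask & cell_mask] = k
        centers.append((cy, cx, a, b, ct, st))

    dna = np.full(shape, background, float)
    egfr = np.full(shape, background, float)
    marker1 = np.full(shape, background, float)
    marker2 = np.full(shape, background, float)
    dna[nucleus_labels > 0] += 120.0
    egfr[cell_labels > 0] += 40.0
    marker1[cell_labels > 0] += 25.0
    marker2[cell_labels > 0] += 25.0

    spot_coords = {"EGFR": [], "Tfn": []}
    counts_out = {"EGFR": [], "Tfn": []}
    for k in range(1, n_cells + 1):
        cy, cx, a, b, ct, st = centers[k - 1]
        n_spots = int(spot_counts[k - 1])
        coords = []
        for s in range(n_spots):
            # alternate shells: perinuclear (just outside the nucleus)
            # vs peripheral, according to perinuclear_fraction
            peri = rng.uniform() < perinuclear_fraction
            radial = rng.uniform(0.25, 0.45) if peri else rng.uniform(0.6, 0.85)
            ang = rng.uniform(0, 2 * np.pi)
            du = radial * a * np.cos(ang)
            dv = radial * b * np.sin(ang)
            r = cy + du * st + dv * ct
            c = cx + du * ct - dv * st
            r = int(round(min(max(r, 0), h - 1)))
            c = int(round(min(max(c, 0), w - 1)))
            if cell_labels[r, c] != k:     # clamp pushed it out: recenter
                r, c = int(round(cy)), int(round(cx))
            coords.append((r, c))
            blob = 90.0 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2)
                                 / (2 * spot_sigma ** 2))
            egfr += blob
        spot_coords["EGFR"].append(np.array(coords, dtype=int).reshape(-1, 2))
        counts_out["EGFR"].append(n_spots)
        spot_coords["Tfn"].append(np.empty((0, 2), dtype=int))
        counts_out["Tfn"].append(0)

    channels = {"DNA": dna, "EGFR": egfr, "Tfn": marker1, "pAkt": marker2}
    if noise_sd > 0:
        for name in channels:
            channels[name] = np.clip(
                channels[name] + rng.normal(0, noise_sd, shape), 0, None)
    return SyntheticCellImage(channels=channels,
                              nucleus_labels=nucleus_labels,
                              cell_labels=cell_labels,
                              spot_coords=spot_coords,
                              spot_counts=counts_out)


def _render_batch_images(config: SyntheticPanelConfig,
                         archetype: MechanismArchetype, potency: float,
                         time_min: float, rng: np.random.Generator) -> list:
    """Images for one batch: enough fields to cover the requested cells.

    Archetype effects are expressed coarsely in image mode: the
    perinuclear spot fraction follows the control trafficking schedule and
    is halved by trafficking-blocking archetypes; spot rates follow the
    archetype's perinuclear endosome-count shift.
    """
    peri_sched = np.array([0.25, 0.45, 0.6, 0.45, 0.35])
    peri = float(np.interp(time_min, _ANCHOR_T, peri_sched))
    shift, _ = archetype.effect("perinuclear_EGFR_endosome_count", time_min)
    ratio_shift, _ = archetype.effect("ratio_perinuclear_PM_EGFR", time_min)
    peri = float(np.clip(peri * (1.0 + 0.4 * ratio_shift * potency), 0.05, 0.95))
    lam = max(5.0 + shift * potency * np.sqrt(5.0), 0.05)
    n_fields = int(np.ceil(config.n_cells_per_condition
                           / config.cells_per_image))
    out = []
    for _ in range(n_fields):
        n = config.cells_per_image
        counts = rng.poisson(lam, size=n)
        out.append(render_cell_image(
            n, counts, shape=config.image_shape,
            seed=int(rng.integers(0, 2**31 - 1)),
            noise_sd=1.0, perinuclear_fraction=peri))
    return out
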