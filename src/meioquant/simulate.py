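"""Synthetic gonads, count tables, and image stacks with ground truth.

The generator reproduces the statistical structure the analysis
assumes, so every downstream stage can be validated against known
truth:

* six chromosome pairs per nucleus, each independently receiving at
  most one crossover-designated focus (complete interference: never
  more than one designated site per pair);
* per-focus Bernoulli maturation with probability ``p_success``, so
  the chiasma count is a binomial thinning of the focus count;
* DAPI bodies at diakinesis = 12 − matured chiasmata, with an optional
  merging artifact emulating touching chromosomes scored as one body;
* stage-dependent homolog pairing along a normalized gonad axis, one
  probability per zone;
* 3D image stacks with nuclei as ellipsoids in a DAPI-like channel,
  foci as anisotropic Gaussian spots, and Poisson noise.

All randomness flows through one ``numpy.random.Generator`` seeded from
the configuration, so identical configurations reproduce identical
gonads bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .pairing import NucleusRecord

__all__ = [
    "SimulationConfig",
    "SyntheticGonad",
    "simulate_cosa_and_dapi",
    "simulate_pairing_gonad",
    "render_image_stack",
]

from .chiasma import CountDistribution, N_CHROMOSOME_PAIRS, DIPLOID_BODIES


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic gonad generator.

    Probabilities are per chromosome pair (``p_designate``), per focus
    (``p_success``) or per body pair (``p_merge``).  ``pairing_curve``
    gives, zone by zone, the probability that a nucleus in that zone
    has its monitored locus paired.  Image parameters describe the
    rendered point-spread function (Gaussian sigmas, nm), spot
    amplitude (photons) and Poisson background rate; ``voxel_size`` is
    (z, y, x) in nm — 125 nm axial spacing matching 3D acquisition
    conventions for this tissue.
    """

    n_gonads: int = 6
    nuclei_per_gonad: int = 227
    n_chromosome_pairs: int = N_CHROMOSOME_PAIRS
    p_designate: float = 1.0
    p_success: float = 1.0
    p_merge: float = 0.0
    pairing_curve: Tuple[float, ...] = (0.35, 0.75, 0.95, 1.0, 1.0)
    focus_intensity: float = 150.0
    psf_sigma_xy_nm: float = 130.0
    psf_sigma_z_nm: float = 300.0
    noise_rate: float = 5.0
    voxel_size: Tuple[float, float, float] = (125.0, 100.0, 100.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_designate", "p_success", "p_merge"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if len(self.pairing_curve) == 0:
            raise ValueError("pairing_curve needs at least one zone probability")
        for v in self.pairing_curve:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"pairing_curve values must lie in [0, 1], got {v}")
        if self.n_gonads < 1 or self.nuclei_per_gonad < 1 or self.n_chromosome_pairs < 1:
            raise ValueError("counts must be >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")
        if self.noise_rate < 0 or self.focus_intensity < 0:
            raise ValueError("intensities and noise rate must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class SyntheticGonad:
    """A ground-truth gonad: nuclei with true states plus geometry."""

    nuclei: List[NucleusRecord]
    gonad_length_um: float = 100.0
    transition_start: float = 0.1
    transition_end: float = 0.25
    cellularization_start: float = 1.0

    def to_frame(self) -> pd.DataFrame:
        """Per-nucleus table of the ground-truth fields."""
        n_zones = 5
        rows = []
        for r in self.nuclei:
            rows.append(
                {
                    "gonad_id": r.gonad_id,
                    "nucleus_id": r.nucleus_id,
                    "axial_pos": r.axial_pos,
                    "stage": r.stage,
                    "k_true": r.k_true,
                    "matured_true": r.matured_true,
                    "dapi_count": r.dapi_count,
                    "paired_true": r.paired_true,
                    "zone": min(int(r.axial_pos * n_zones), n_zones - 1),
                }
            )
        return pd.DataFrame(rows)


def _stage_for_position(pos: float, gonad: "SyntheticGonad | None" = None) -> str:
    ts = gonad.transition_start if gonad else 0.1
    te = gonad.transition_end if gonad else 0.25
    if pos < ts:
        return "premeiotic"
    if pos < te:
        return "transition"
    if pos < 0.6:
        return "early_pachytene"
    if pos < 0.95:
        return "late_pachytene"
    return "diakinesis"


def _apply_merging(n_bodies: int, p_merge: float, rng: np.random.Generator) -> int:
    """Merge touching diakinesis bodies.

    Bodies are paired off at random (disjoint pairs) and each pair
    independently collapses into one scored body with probability
    ``p_merge``; chains of more than two touching chromosomes are not
    modelled.  With ``p_merge = 0`` the count is untouched.
    """
    if p_merge == 0.0 or n_bodies < 2:
        return n_bodies
    n_pairs = n_bodies // 2
    merges = rng.binomial(n_pairs, p_merge)
    return n_bodies - int(merges)


def simulate_cosa_and_dapi(
    config: SimulationConfig,
) -> Tuple[CountDistribution, CountDistribution, List[NucleusRecord]]:
    """Simulate focus designation and chiasma maturation per nucleus.

    Each of the ``n_chromosome_pairs`` pairs independently receives one
    designated focus with probability ``p_designate`` (never more than
    one per pair), each focus matures with probability ``p_success``,
    and the scored DAPI-body count is ``2*pairs − matured`` with the
    optional merging artifact applied.  Returns the tallied focus-count
    distribution, the chiasma distribution inferred as ``12 − DAPI``
    from the *merged* counts, and the per-nucleus records with ground
    truth.
    """
    rng = config.rng()
    kmax = config.n_chromosome_pairs
    records: List[NucleusRecord] = []
    cosa_tally: Dict[int, float] = {}
    chiasma_tally: Dict[int, float] = {}
    for g in range(config.n_gonads):
        gid = f"g{g:02d}"
        positions = np.sort(rng.uniform(0.0, 1.0, config.nuclei_per_gonad))
        k = rng.binomial(kmax, config.p_designate, config.nuclei_per_gonad)
        matured = rng.binomial(k, config.p_success)
        for i in range(config.nuclei_per_gonad):
            dapi_true = 2 * kmax - int(matured[i])
            dapi_obs = _apply_merging(dapi_true, config.p_merge, rng)
            rec = NucleusRecord(
                gonad_id=gid,
                nucleus_id=f"{gid}_n{i:04d}",
                axial_pos=float(positions[i]),
                stage="diakinesis",
                cosa_count=int(k[i]),
                dapi_count=dapi_obs,
                k_true=int(k[i]),
                matured_true=int(matured[i]),
            )
            records.append(rec)
            cosa_tally[rec.cosa_count] = cosa_tally.get(rec.cosa_count, 0.0) + 1.0
            inferred = 2 * kmax - dapi_obs
            chiasma_tally[inferred] = chiasma_tally.get(inferred, 0.0) + 1.0
    return (
        CountDistribution(cosa_tally, k_max=kmax),
        CountDistribution(chiasma_tally, k_max=kmax),
        records,
    )


def simulate_pairing_gonad(config: SimulationConfig) -> SyntheticGonad:
    """Simulate one gonad's worth of locus-pairing observations.

    Nuclei are placed uniformly along the normalized axis; the zone of
    each nucleus (equal-width bins, one per entry of ``pairing_curve``)
    sets its probability of being paired.  A paired nucleus carries two
    locus signals 0.2 µm apart (or one fused signal, 30% of the time);
    an unpaired nucleus carries two signals 1.5–3 µm apart.  Ground
    truth is recorded on every record.
    """
    rng = config.rng()
    n_zones = len(config.pairing_curve)
    if n_zones < 1:
        raise ValueError("pairing_curve must have at least one zone probability")
    nuclei: List[NucleusRecord] = []
    positions = np.sort(rng.uniform(0.0, 1.0, config.nuclei_per_gonad))
    gonad = SyntheticGonad(nuclei=[], gonad_length_um=100.0)
    for i, pos in enumerate(positions):
        zone = min(int(pos * n_zones), n_zones - 1)
        paired = bool(rng.random() < config.pairing_curve[zone])
        center = np.array([2.0, 2.0, pos * gonad.gonad_length_um])
        if paired and rng.random() < 0.3:
            foci = [tuple(center)]
        else:
            sep = rng.uniform(0.05, 0.2) if paired else rng.uniform(1.5, 3.0)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            foci = [
                tuple(center - direction * sep / 2),
                tuple(center + direction * sep / 2),
            ]
        nuclei.append(
            NucleusRecord(
                gonad_id="g00",
                nucleus_id=f"n{i:04d}",
                axial_pos=float(pos),
                stage=_stage_for_position(pos),
                locus_foci=[[tuple(map(float, f)) for f in foci]],
                paired_true=paired,
            )
        )
    gonad.nuclei = nuclei
    return gonad


def _ellipsoid_mask(shape_zyx, center_vox, radii_vox):
    zz, yy, xx = np.ogrid[: shape_zyx[0], : shape_zyx[1], : shape_zyx[2]]
    return (
        ((zz - center_vox[0]) / radii_vox[0]) ** 2
        + ((yy - center_vox[1]) / radii_vox[1]) ** 2
        + ((xx - center_vox[2]) / radii_vox[2]) ** 2
    ) <= 1.0


def render_image_stack(
    config: SimulationConfig,
    n_nuclei: int = 50,
    mean_foci_per_nucleus: float = 5.0,
    nucleus_radius_um: float = 1.5,
    min_focus_separation_um: float = 0.7,
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame, pd.DataFrame]:
    """Render a two-channel 3D stack of nuclei and foci with truth tables.

    Nuclei are laid out on a jittered grid along the (x) gonad axis and
    rendered as filled ellipsoids in the DAPI channel; each nucleus
    receives a Poisson number of foci (mean ``mean_foci_per_nucleus``)
    placed well inside the nuclear volume and rendered as anisotropic
    3D Gaussians of the configured PSF sigmas in the signal channel.
    Poisson shot noise at ``noise_rate`` background counts per voxel is
    applied to both channels.

    Returns ``(stacks, nucleus_truth, focus_truth)`` where ``stacks``
    maps channel name to a float ZYX array and the truth tables carry
    physical coordinates in µm (voxel center convention:
    ``coord = (index + 0.5) * voxel_size``).
    """
    rng = config.rng()
    vz, vy, vx = (v / 1000.0 for v in config.voxel_size)  # µm per voxel
    r = nucleus_radius_um
    # jittered grid: rows of 10 nuclei along x
    n_cols = min(10, n_nuclei)
    n_rows = int(np.ceil(n_nuclei / n_cols))
    pitch = 2.0 * r + 1.2
    margin = r + 0.8
    size_x = margin * 2 + (n_cols - 1) * pitch
    size_y = margin * 2 + (n_rows - 1) * pitch
    size_z = 2 * r + 1.6
    shape = (
        int(np.ceil(size_z / vz)),
        int(np.ceil(size_y / vy)),
        int(np.ceil(size_x / vx)),
    )
    if min(shape) < 2:
        raise ValueError(f"voxel size {config.voxel_size} yields a degenerate stack {shape}")

    dapi = np.zeros(shape)
    signal = np.zeros(shape)
    nuc_rows, focus_rows = [], []
    sig_z = config.psf_sigma_z_nm / 1000.0
    sig_xy = config.psf_sigma_xy_nm / 1000.0

    fid = 0
    for n in range(n_nuclei):
        row, col = divmod(n, n_cols)
        center = np.array(
            [
                size_z / 2 + rng.uniform(-0.2, 0.2),
                margin + row * pitch + rng.uniform(-0.3, 0.3),
                margin + col * pitch + rng.uniform(-0.3, 0.3),
            ]
        )
        center_vox = center / np.array([vz, vy, vx]) - 0.5
        radii_vox = np.array([r / vz, r / vy, r / vx])
        dapi[_ellipsoid_mask(shape, center_vox, radii_vox)] += 80.0
        axial = center[2] / size_x
        nuc_rows.append(
            {
                "nucleus_id": f"n{n:03d}",
                "z_um": center[0],
                "y_um": center[1],
                "x_um": center[2],
                "axial_pos": axial,
                "n_foci": 0,
            }
        )
        n_foci = rng.poisson(mean_foci_per_nucleus)
        nuc_rows[-1]["n_foci"] = int(n_foci)
        placed: List[np.ndarray] = []
        for _ in range(n_foci):
            # uniform in a ball of 0.6 r so the focus sits inside the hull;
            # foci mark distinct chromosomal sites, so enforce a minimum
            # separation (rejection sampling, capped attempts)
            fpos = None
            for _attempt in range(200):
                offset = rng.uniform(-1, 1, 3)
                if np.sum(offset**2) > 1:
                    continue
                cand = center + offset * 0.6 * r
                if all(
                    np.linalg.norm(cand - q) >= min_focus_separation_um for q in placed
                ):
                    fpos = cand
                    break
            if fpos is None:
                nuc_rows[-1]["n_foci"] -= 1
                continue
            placed.append(fpos)
            focus_rows.append(
                {
                    "focus_id": fid,
                    "nucleus_id": f"n{n:03d}",
                    "z_um": fpos[0],
                    "y_um": fpos[1],
                    "x_um": fpos[2],
                }
            )
            fid += 1
            _add_gaussian_spot(
                signal, fpos, (sig_z, sig_xy, sig_xy), (vz, vy, vx), config.focus_intensity
            )

    if config.noise_rate > 0:
        dapi = rng.poisson(dapi + config.noise_rate).astype(float)
        signal = rng.poisson(signal + config.noise_rate).astype(float)
    stacks = {"dapi": dapi, "signal": signal}
    return stacks, pd.DataFrame(nuc_rows), pd.DataFrame(focus_rows)


def _add_gaussian_spot(stack, pos_um, sigma_um, voxel_um, amplitude) -> None:
    """Accumulate one anisotropic 3D Gaussian into ``stack`` in place."""
    vz, vy, vx = voxel_um
    center_vox = np.array([pos_um[0] / vz, pos_um[1] / vy, pos_um[2] / vx]) - 0.5
    half = np.array(
        [4 * sigma_um[0] / vz, 4 * sigma_um[1] / vy, 4 * sigma_um[2] / vx]
    )
    lo = np.maximum(np.floor(center_vox - half).astype(int), 0)
    hi = np.minimum(np.ceil(center_vox + half).astype(int) + 1, stack.shape)
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.meshgrid(
        np.arange(lo[0], hi[0]), np.arange(lo[1], hi[1]), np.arange(lo[2], hi[2]),
        indexing="ij",
    )
    d2 = (
        ((zz - center_vox[0]) * vz / sigma_um[0]) ** 2
        + ((yy - center_vox[1]) * vy / sigma_um[1]) ** 2
        + ((xx - center_vox[2]) * vx / sigma_um[2]) ** 2
    )
    stack[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] += amplitude * np.exp(-d2 / 2.0)
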