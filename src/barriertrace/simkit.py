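"""Synthetic photobleaching, photoconversion, image and pedigree data.

The generative model is the one the downstream analysis assumes: a budded
yeast cell whose reporter pool occupies three well-mixed compartments —
the bleach ROI, the rest of the ROI's cell body, and the other cell body
(mother or bud) — connected by first-order exchange.  The bud neck acts as
the bottleneck: the rate constant coupling the two cell bodies is
proportional to the permeability of the lateral diffusion barrier, so a
strong barrier means slow fluorescence loss in the bud during mother-side
FLIP and a high Barrier Index downstream.

Between acquisitions the mobile reporter concentrations ``c`` evolve as a
linear system ``dc/dt = A c`` propagated exactly with the matrix
exponential.  Bleach or photoconversion pulses are instantaneous
multiplicative events on the ROI state; every acquisition itself bleaches
all compartments by a small fraction (which is why the analysis normalizes
to unbleached neighbor cells).  An immobile fraction of the reporter never
exchanges between states but is bleached like everything else, which is
what produces FRAP plateaus below the pre-bleach level.

All stochasticity flows through :class:`NoiseModel` seeds; identical
parameters and seed give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "CompartmentModel",
    "BleachProtocol",
    "NoiseModel",
    "TraceBundle",
    "NeckProfileSample",
    "SpotImage",
    "PedigreeSample",
    "simulate_trace_bundle",
    "simulate_photoconversion",
    "simulate_neck_profile",
    "simulate_spot_image",
    "simulate_pedigree",
    "default_model",
    "default_flip_protocol",
    "default_frap_protocol",
    "default_photoconversion_protocol",
    "WILD_TYPE_EXCHANGE_RATE",
    "KAR2_LIKE_INTRA_MIXING",
    "WILD_TYPE_HAZARD",
    "STRESSED_HAZARD",
    "INITIAL_INTENSITY",
]

#: Reporter concentration (a.u.) every compartment starts from.
INITIAL_INTENSITY = 1000.0

#: Mother<->bud exchange rate (1/s) calibrated so that, with the default
#: FLIP protocol, the noiseless pipeline yields mother half-loss ~10 s and
#: a Barrier Index ~7 (a wild-type-like cER barrier).  Weakened-barrier
#: conditions are modelled by multiplying this rate.
WILD_TYPE_EXCHANGE_RATE = 0.0115

#: ROI<->compartment mixing rate (1/s) emulating a luminal chaperone-like
#: reporter in an unstressed mother: with the default FRAP protocol the
#: fitted recovery half-time comes out near 8.5 s.  Client-occupied
#: (ER-stressed) chaperone mobility is emulated by scaling this down.
KAR2_LIKE_INTRA_MIXING = 0.0643

#: Per-division death probabilities whose geometric lifespans have median
#: 26 (unstressed) and 19 (ER-stressed) generations.
WILD_TYPE_HAZARD = 0.0268
STRESSED_HAZARD = 0.0368

_MODES = ("flip_repeated", "frap_single", "photoconvert_single")
_COMPARTMENTS = ("mother", "bud")


@dataclass(frozen=True)
class CompartmentModel:
    """Physical parameters of the two-body, three-state exchange model.

    Volumes are relative (only ratios matter).  ``exchange_rate`` is the
    first-order relaxation rate (1/s) of the non-ROI cell body toward the
    compartment across the bud neck; it is proportional to barrier
    permeability.  ``intra_mixing_rate`` plays the same role for the bleach
    ROI inside its own cell body.  ``acquisition_bleach_fraction`` is the
    fractional loss per acquired frame in every compartment, and
    ``immobile_fraction`` the share of reporter exempt from exchange (but
    not from bleaching).
    """

    volume_mother: float = 1.0
    volume_bud: float = 0.35
    exchange_rate: float = WILD_TYPE_EXCHANGE_RATE
    intra_mixing_rate: float = 1.0
    acquisition_bleach_fraction: float = 0.002
    immobile_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in ("volume_mother", "volume_bud"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("exchange_rate", "intra_mixing_rate"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        for name in ("acquisition_bleach_fraction", "immobile_fraction"):
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass(frozen=True)
class BleachProtocol:
    """Acquisition and bleaching schedule.

    ``pulse_frames`` lists the frame indices after whose acquisition a
    bleach (or photoconversion) pulse is applied, so a pulse at frame 0
    leaves frame 0 itself unbleached — the convention under which the
    first FLIP point is the 100 % reference.  ``roi_fraction`` is the share
    of the ROI compartment's volume inside the bleached region.
    """

    mode: str
    frame_interval: float
    n_frames: int
    pulse_frames: tuple[int, ...]
    pulse_efficiency: float
    roi_compartment: str = "mother"
    roi_fraction: float = 0.15

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if not (np.isfinite(self.frame_interval) and self.frame_interval > 0):
            raise ValueError("frame_interval must be finite and > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        pf = tuple(int(k) for k in self.pulse_frames)
        object.__setattr__(self, "pulse_frames", pf)
        if any(k < 0 or k >= self.n_frames for k in pf):
            raise ValueError("pulse_frames must lie in [0, n_frames)")
        if self.mode == "flip_repeated" and len(pf) < 2:
            raise ValueError("flip_repeated needs at least 2 pulse frames")
        if self.mode in ("frap_single", "photoconvert_single") and len(pf) != 1:
            raise ValueError(f"{self.mode} needs exactly 1 pulse frame")
        if not (np.isfinite(self.pulse_efficiency) and 0.0 <= self.pulse_efficiency <= 1.0):
            raise ValueError("pulse_efficiency must lie in [0, 1]")
        if self.roi_compartment not in _COMPARTMENTS:
            raise ValueError("roi_compartment must be 'mother' or 'bud'")
        if not (np.isfinite(self.roi_fraction) and 0.0 <= self.roi_fraction < 1.0):
            raise ValueError("roi_fraction must lie in [0, 1)")
        if pf and self.roi_fraction == 0.0:
            raise ValueError("roi_fraction = 0 with pulses scheduled")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass(frozen=True)
class NoiseModel:
    """Instrumental noise: additive background plus multiplicative readout.

    Noise acts on measured traces only, never on the underlying state.
    ``background_level`` is added to every signal ROI and also recorded as
    its own trace (with sd ``background_sd``); ``multiplicative_cv`` is the
    coefficient of variation of the intensity readout.
    """

    background_level: float = 50.0
    background_sd: float = 2.0
    multiplicative_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_level", "background_sd", "multiplicative_cv"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    @classmethod
    def none(cls, seed: int = 0) -> "NoiseModel":
        """Noise-free measurement (still carries a seed for determinism)."""
        return cls(background_level=0.0, background_sd=0.0, multiplicative_cv=0.0, seed=seed)


@dataclass
class TraceBundle:
    """One cell's experiment: mother, bud, five neighbor controls, background."""

    times: np.ndarray
    mother: np.ndarray
    bud: np.ndarray
    controls: np.ndarray  # shape (5, n_frames)
    background: np.ndarray
    channel: str = "green"
    cell_id: str = "cell0"
    ground_truth: Optional[CompartmentModel] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mother = np.asarray(self.mother, dtype=float)
        self.bud = np.asarray(self.bud, dtype=float)
        self.controls = np.atleast_2d(np.asarray(self.controls, dtype=float))
        self.background = np.asarray(self.background, dtype=float)
        n = self.times.size
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.controls.shape[0] != 5:
            raise ValueError("exactly five control traces are required")
        for name in ("mother", "bud", "background"):
            if getattr(self, name).shape != (n,):
                raise ValueError(f"{name} trace length does not match times")
        if self.controls.shape[1] != n:
            raise ValueError("control trace length does not match times")
        if self.channel not in ("green", "red"):
            raise ValueError("channel must be 'green' or 'red'")


@dataclass
class NeckProfileSample:
    """Cortical intensity transect through the bud neck."""

    positions: np.ndarray  # micrometers, strictly increasing
    intensities: np.ndarray
    true_class: Optional[str] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.positions.size < 7:
            raise ValueError("profile needs at least 7 samples")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if self.intensities.shape != self.positions.shape:
            raise ValueError("positions and intensities differ in length")
        if self.true_class is not None and self.true_class not in ("total", "partial", "none"):
            raise ValueError("true_class must be 'total', 'partial' or 'none'")


@dataclass
class SpotImage:
    """Synthetic widefield image of diffraction-limited aggregates."""

    pixels: np.ndarray
    mother_mask: np.ndarray
    bud_mask: np.ndarray
    psf_sigma: float = 1.5
    true_spots: list[tuple[int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mother_mask = np.asarray(self.mother_mask, dtype=bool)
        self.bud_mask = np.asarray(self.bud_mask, dtype=bool)
        if self.mother_mask.shape != self.pixels.shape or self.bud_mask.shape != self.pixels.shape:
            raise ValueError("masks must match image shape")
        if np.any(self.mother_mask & self.bud_mask):
            raise ValueError("mother and bud masks must be disjoint")


@dataclass
class PedigreeSample:
    """Completed division counts of individually followed mother cells."""

    divisions: np.ndarray
    hazard_params: Optional[tuple[float, ...]] = None
    strain: str = "strain0"

    def __post_init__(self) -> None:
        self.divisions = np.asarray(self.divisions, dtype=int)
        if self.divisions.size and self.divisions.min() < 1:
            raise ValueError("division counts must be >= 1")


# ---------------------------------------------------------------------------
# exchange dynamics


def _state_volumes(model: CompartmentModel, protocol: BleachProtocol) -> np.ndarray:
    """Volumes of [ROI, rest-of-ROI-compartment, other compartment]."""
    if protocol.roi_compartment == "mother":
        v_roi_comp, v_other = model.volume_mother, model.volume_bud
    else:
        v_roi_comp, v_other = model.volume_bud, model.volume_mother
    f = protocol.roi_fraction
    return np.array([f * v_roi_comp, (1.0 - f) * v_roi_comp, v_other])


def rate_matrix(model: CompartmentModel, protocol: BleachProtocol) -> np.ndarray:
    """Generator A of dc/dt = A c for the mobile concentrations.

    Exchange between two states is a conductance g (volume/time) moving
    material down the concentration difference, so the volume-weighted
    total is conserved exactly (columns of A are in the kernel of the
    volume vector).  The ROI couples to the rest of its compartment with
    g = intra_mixing_rate * v_roi; the two cell bodies couple with
    g = exchange_rate * v_other, making ``exchange_rate`` the relaxation
    rate of the distal compartment toward the ROI-side body.
    """
    v = _state_volumes(model, protocol)
    A = np.zeros((3, 3))
    if v[0] > 0.0:
        g = model.intra_mixing_rate * v[0]
        A[0, 0] -= g / v[0]
        A[0, 1] += g / v[0]
        A[1, 1] -= g / v[1]
        A[1, 0] += g / v[1]
    g = model.exchange_rate * v[2]
    A[1, 1] -= g / v[1]
    A[1, 2] += g / v[1]
    A[2, 2] -= g / v[2]
    A[2, 1] += g / v[2]
    return A


def _propagate_states(
    model: CompartmentModel,
    protocol: BleachProtocol,
    initial: Sequence[np.ndarray],
) -> list[np.ndarray]:
    """Evolve (mobile, immobile) state pairs through the whole protocol.

    ``initial`` is a flat sequence alternating mobile and immobile vectors
    (one pair per channel).  Returns per-pair concentration arrays of shape
    (n_frames, 3) holding mobile + immobile at each acquisition.
    """
    A = rate_matrix(model, protocol)
    P = expm(A * protocol.frame_interval)
    q = 1.0 - model.acquisition_bleach_fraction
    keep = 1.0 - protocol.pulse_efficiency
    pulses = set(protocol.pulse_frames)
    pairs = [(np.array(m, dtype=float), np.array(i, dtype=float)) for m, i in initial]
    out = [np.empty((protocol.n_frames, 3)) for _ in pairs]
    for k in range(protocol.n_frames):
        if k > 0:
            pairs = [(P @ m, i) for m, i in pairs]
        pairs = [(m * q, i * q) for m, i in pairs]
        for rec, (m, i) in zip(out, pairs):
            rec[k] = m + i
        if k in pulses:
            for m, i in pairs:
                m[0] *= keep
                i[0] *= keep
    return out


def _measured_compartments(
    conc: np.ndarray, model: CompartmentModel, protocol: BleachProtocol
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-intensity readouts (mother, bud) from state concentrations."""
    v = _state_volumes(model, protocol)
    roi_side = (conc[:, 0] * v[0] + conc[:, 1] * v[1]) / (v[0] + v[1])
    other = conc[:, 2]
    if protocol.roi_compartment == "mother":
        return roi_side, other
    return other, roi_side


def _control_traces(model: CompartmentModel, n_frames: int, rng: np.random.Generator) -> np.ndarray:
    """Five unpulsed neighbor mothers: acquisition bleaching only.

    Each neighbor gets a fixed brightness offset (cell-to-cell expression
    variation) so the per-frame control mean is not trivially flat.
    """
    q = 1.0 - model.acquisition_bleach_fraction
    base = INITIAL_INTENSITY * np.clip(1.0 + 0.1 * rng.standard_normal(5), 0.2, None)
    decay = q ** np.arange(1, n_frames + 1)
    return base[:, None] * decay[None, :]


def _read_out(signal: np.ndarray, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    """Apply multiplicative readout noise and additive background."""
    mult = 1.0 + noise.multiplicative_cv * rng.standard_normal(signal.shape)
    bg = noise.background_level + noise.background_sd * rng.standard_normal(signal.shape)
    return np.clip(signal * mult + bg, 0.0, None)


def _background_trace(n: int, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    return np.clip(
        noise.background_level + noise.background_sd * rng.standard_normal(n), 0.0, None
    )


def simulate_trace_bundle(
    model: CompartmentModel,
    protocol: BleachProtocol,
    noise: NoiseModel,
    cell_id: str = "cell0",
) -> TraceBundle:
    """Simulate one FLIP or FRAP cell with five neighbor controls.

    The mobile pool evolves by matrix-exponential propagation between
    frames; each scheduled pulse removes ``pulse_efficiency`` of the ROI
    states, each acquisition removes ``acquisition_bleach_fraction``
    everywhere (controls included).  Noise is applied to the measured
    traces last.

    Readout follows the experiment: FLIP reports whole-compartment mean
    intensities (mother and bud), whereas FRAP reports the bleached ROI
    itself for the ROI compartment (recovery is exchange with the rest of
    that compartment) and the compartment mean for the other.
    """
    if protocol.mode not in ("flip_repeated", "frap_single"):
        raise ValueError("simulate_trace_bundle handles flip_repeated or frap_single")
    c0 = INITIAL_INTENSITY
    mob0 = np.full(3, (1.0 - model.immobile_fraction) * c0)
    imm0 = np.full(3, model.immobile_fraction * c0)
    (conc,) = _propagate_states(model, protocol, [(mob0, imm0)])
    mother, bud = _measured_compartments(conc, model, protocol)
    if protocol.mode == "frap_single":
        if protocol.roi_compartment == "mother":
            mother = conc[:, 0]
        else:
            bud = conc[:, 0]

    rng = np.random.default_rng(noise.seed)
    controls = _control_traces(model, protocol.n_frames, rng)
    return TraceBundle(
        times=protocol.times,
        mother=_read_out(mother, noise, rng),
        bud=_read_out(bud, noise, rng),
        controls=_read_out(controls, noise, rng),
        background=_background_trace(protocol.n_frames, noise, rng),
        channel="green",
        cell_id=cell_id,
        ground_truth=model,
    )


def simulate_photoconversion(
    model: CompartmentModel,
    protocol: BleachProtocol,
    noise: NoiseModel,
    preconverted_fraction: float = 0.02,
    cell_id: str = "cell0",
) -> tuple[TraceBundle, TraceBundle]:
    """Simulate a green->red photoconversion chase; returns (green, red).

    The conversion pulse moves ``pulse_efficiency`` of the green ROI signal
    into the red channel in place; both channels then share the exchange
    dynamics.  ``preconverted_fraction`` of the pool starts red everywhere
    (basal conversion / red-channel bleed-through), which keeps the
    pre-conversion red level positive — the reference the chase
    normalization divides by.
    """
    if protocol.mode != "photoconvert_single":
        raise ValueError("protocol.mode must be 'photoconvert_single'")
    if protocol.roi_compartment != "mother":
        raise ValueError("photoconversion ROI must be in the mother")
    if not 0.0 <= preconverted_fraction < 1.0:
        raise ValueError("preconverted_fraction must lie in [0, 1)")

    c0 = INITIAL_INTENSITY
    f_imm = model.immobile_fraction
    green0 = (1.0 - preconverted_fraction) * c0
    red0 = preconverted_fraction * c0

    A = rate_matrix(model, protocol)
    P = expm(A * protocol.frame_interval)
    q = 1.0 - model.acquisition_bleach_fraction
    pulse = protocol.pulse_frames[0]

    g_mob = np.full(3, (1.0 - f_imm) * green0)
    g_imm = np.full(3, f_imm * green0)
    r_mob = np.full(3, (1.0 - f_imm) * red0)
    r_imm = np.full(3, f_imm * red0)
    n = protocol.n_frames
    g_conc = np.empty((n, 3))
    r_conc = np.empty((n, 3))
    for k in range(n):
        if k > 0:
            g_mob = P @ g_mob
            r_mob = P @ r_mob
        g_mob *= q
        g_imm *= q
        r_mob *= q
        r_imm *= q
        g_conc[k] = g_mob + g_imm
        r_conc[k] = r_mob + r_imm
        if k == pulse:
            for src, dst in ((g_mob, r_mob), (g_imm, r_imm)):
                moved = protocol.pulse_efficiency * src[0]
                src[0] -= moved
                dst[0] += moved

    rng = np.random.default_rng(noise.seed)
    bundles = []
    for channel, conc in (("green", g_conc), ("red", r_conc)):
        mother, bud = _measured_compartments(conc, model, protocol)
        controls = _control_traces(model, n, rng)
        if channel == "red":
            controls = controls * preconverted_fraction
        bundles.append(
            TraceBundle(
                times=protocol.times,
                mother=_read_out(mother, noise, rng),
                bud=_read_out(bud, noise, rng),
                controls=_read_out(controls, noise, rng),
                background=_background_trace(n, noise, rng),
                channel=channel,
                cell_id=cell_id,
                ground_truth=model,
            )
        )
    return bundles[0], bundles[1]


# ---------------------------------------------------------------------------
# neck profiles, spot images, pedigrees

_CLASS_DEPTH_RANGES = {"total": (0.7, 1.0), "partial": (0.3, 0.7), "none": (0.0, 0.3)}


def simulate_neck_profile(
    true_class: str,
    depth: float,
    width: float,
    noise: NoiseModel,
    span: float = 4.0,
    n_points: int = 61,
    baseline: float = 100.0,
) -> NeckProfileSample:
    """Cortical transect with a centered inverted-Gaussian neck dip.

    ``depth`` is the relative depth of the exclusion dip (1 = signal falls
    to zero at the neck center); ``width`` its Gaussian sigma in um; the
    transect spans ``span`` um.  The stored class must be consistent with
    the depth under the ratio thresholds the classifier uses (total:
    depth >= 0.7, partial: 0.3 < depth < 0.7, none: depth <= 0.3).
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    if width <= 0:
        raise ValueError("width must be > 0")
    lo, hi = _CLASS_DEPTH_RANGES[true_class]
    ok = (
        (true_class == "total" and depth >= lo)
        or (true_class == "partial" and lo < depth < hi)
        or (true_class == "none" and depth <= hi)
    )
    if not ok:
        raise ValueError(f"depth {depth} inconsistent with class {true_class!r}")
    x = np.linspace(-span / 2.0, span / 2.0, n_points)
    signal = baseline * (1.0 - depth * np.exp(-(x**2) / (2.0 * width**2)))
    rng = np.random.default_rng(noise.seed)
    intensities = _read_out(signal, noise, rng)
    return NeckProfileSample(positions=x, intensities=intensities, true_class=true_class)


def simulate_spot_image(
    n_mother: int,
    n_bud: int,
    psf_sigma: float,
    noise: NoiseModel,
    shape: tuple[int, int] = (96, 144),
    amplitude: float = 400.0,
    max_tries: int = 2000,
) -> SpotImage:
    """Diffraction-limited spots on background inside mother/bud masks.

    Spots are 2-D Gaussians of sigma ``psf_sigma`` placed at least
    4*psf_sigma apart (and clear of mask edges); coordinates and
    compartment labels are stored as ground truth.
    """
    if psf_sigma <= 0:
        raise ValueError("psf_sigma must be > 0")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # mother: large disk on the left; bud: smaller disk on the right
    m_c, m_r = (h // 2, int(w * 0.32)), min(h, w) * 0.30
    b_c, b_r = (h // 2, int(w * 0.80)), min(h, w) * 0.16
    mother_mask = (yy - m_c[0]) ** 2 + (xx - m_c[1]) ** 2 <= m_r**2
    bud_mask = (yy - b_c[0]) ** 2 + (xx - b_c[1]) ** 2 <= b_r**2
    bud_mask &= ~mother_mask

    rng = np.random.default_rng(noise.seed)
    min_sep = 4.0 * psf_sigma
    margin = 2.0 * psf_sigma
    spots: list[tuple[int, int, str]] = []

    def _place(mask: np.ndarray, count: int, label: str) -> None:
        centre = (m_c, m_r) if label == "mother" else (b_c, b_r)
        (cy, cx), radius = centre
        placed = 0
        for _ in range(max_tries):
            if placed == count:
                return
            r = (radius - margin) * math.sqrt(rng.random())
            theta = 2.0 * math.pi * rng.random()
            y, x = int(round(cy + r * math.sin(theta))), int(round(cx + r * math.cos(theta)))
            if not (0 <= y < h and 0 <= x < w and mask[y, x]):
                continue
            if all(math.hypot(y - sy, x - sx) >= min_sep for sy, sx, _ in spots):
                spots.append((y, x, label))
                placed += 1
        if placed < count:
            raise ValueError(f"could not place {count} spots in {label} mask at spacing {min_sep}")

    _place(mother_mask, n_mother, "mother")
    _place(bud_mask, n_bud, "bud")

    signal = np.zeros(shape)
    for y, x, _ in spots:
        signal += amplitude * np.exp(
            -((yy - y) ** 2 + (xx - x) ** 2) / (2.0 * psf_sigma**2)
        )
    pixels = _read_out(signal, noise, rng)
    return SpotImage(
        pixels=pixels,
        mother_mask=mother_mask,
        bud_mask=bud_mask,
        psf_sigma=psf_sigma,
        true_spots=spots,
    )


def simulate_pedigree(
    n_mothers: int,
    hazard: Sequence[float] | float,
    seed: int,
    strain: str = "strain0",
    max_divisions: int = 10000,
) -> PedigreeSample:
    """Draw per-mother division counts by sequential Bernoulli death trials.

    ``hazard`` gives the probability of dying at each successive division;
    the last value persists beyond the schedule (a constant hazard yields
    geometric lifespans).  Every mother is followed to death (no
    censoring).
    """
    if n_mothers < 1:
        raise ValueError("n_mothers must be >= 1")
    hazard_arr = np.atleast_1d(np.asarray(hazard, dtype=float))
    if hazard_arr.size == 0:
        raise ValueError("hazard schedule must not be empty")
    if np.any((hazard_arr <= 0) | (hazard_arr > 1)):
        raise ValueError("hazard values must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    divisions = np.zeros(n_mothers, dtype=int)
    alive = np.ones(n_mothers, dtype=bool)
    for k in range(max_divisions):
        if not alive.any():
            break
        h = hazard_arr[min(k, hazard_arr.size - 1)]
        dies = rng.random(n_mothers) < h
        divisions[alive & dies] = k + 1
        alive &= ~dies
    else:
        raise RuntimeError("some mothers survived past max_divisions; hazard too small")
    return PedigreeSample(
        divisions=divisions, hazard_params=tuple(hazard_arr.tolist()), strain=strain
    )


# ---------------------------------------------------------------------------
# shipped wild-type-like calibration


def default_model(exchange_rate: float = WILD_TYPE_EXCHANGE_RATE) -> CompartmentModel:
    """Wild-type-like cell; pass a larger ``exchange_rate`` for weakened barriers."""
    return CompartmentModel(exchange_rate=exchange_rate)


def default_flip_protocol() -> BleachProtocol:
    """Repeated mother-side bleaching: 1 s frames, 200 frames, pulse every frame."""
    return BleachProtocol(
        mode="flip_repeated",
        frame_interval=1.0,
        n_frames=200,
        pulse_frames=tuple(range(0, 199)),
        pulse_efficiency=0.55,
        roi_compartment="mother",
        roi_fraction=0.15,
    )


def default_frap_protocol(roi_compartment: str = "mother") -> BleachProtocol:
    """Single bleach after 5 pre-bleach frames; 0.5 s frames, 90 frames."""
    return BleachProtocol(
        mode="frap_single",
        frame_interval=0.5,
        n_frames=90,
        pulse_frames=(4,),
        pulse_efficiency=0.8,
        roi_compartment=roi_compartment,
        roi_fraction=0.25,
    )


def default_photoconversion_protocol() -> BleachProtocol:
    """One conversion in the mother, then a frame every 20 s for 2 min."""
    return BleachProtocol(
        mode="photoconvert_single",
        frame_interval=20.0,
        n_frames=8,
        pulse_frames=(0,),
        pulse_efficiency=0.9,
        roi_compartment="mother",
        roi_fraction=0.5,
    )
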