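"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from barriertrace import simkit
from barriertrace.simkit import BleachProtocol, CompartmentModel, NoiseModel


@pytest.fixture
def no_noise() -> NoiseModel:
    return NoiseModel.none()


@pytest.fixture
def wt_model() -> CompartmentModel:
    return simkit.default_model()


@pytest.fixture
def flip_protocol() -> BleachProtocol:
    return simkit.default_flip_protocol()


def short_flip_protocol(n_frames: int = 20, frame_interval: float = 1.0) -> BleachProtocol:
    return BleachProtocol(
        mode="flip_repeated",
        frame_interval=frame_interval,
        n_frames=n_frames,
        pulse_frames=tuple(range(n_frames - 1)),
        pulse_efficiency=0.55,
        roi_compartment="mother",
        roi_fraction=0.15,
    )


def brute_force_traces(
    model: CompartmentModel, protocol: BleachProtocol, substeps: int = 1000
) -> tuple[np.ndarray, np.ndarray]:
    """Independent fine-step integration of the exchange system.

    Re-derives the coupled ODEs from scratch (conductance bookkeeping, not
    the package's rate matrix) and integrates them with classical
    fixed-step RK4 at dt = frame_interval / substeps, replaying the same
    pulse/acquisition events.  Returns noiseless (mother, bud) readouts.
    """
    f = protocol.roi_fraction
    if protocol.roi_compartment == "mother":
        v = np.array([f * model.volume_mother, (1 - f) * model.volume_mother, model.volume_bud])
    else:
        v = np.array([f * model.volume_bud, (1 - f) * model.volume_bud, model.volume_mother])
    g_mix = model.intra_mixing_rate * v[0]
    g_neck = model.exchange_rate * v[2]

    def deriv(c: np.ndarray) -> np.ndarray:
        flux_mix = g_mix * (c[1] - c[0])  # into ROI
        flux_neck = g_neck * (c[2] - c[1])  # into rest
        return np.array(
            [
                flux_mix / v[0] if v[0] > 0 else 0.0,
                (-flux_mix + flux_neck) / v[1],
                -flux_neck / v[2],
            ]
        )

    dt = protocol.frame_interval / substeps
    q = 1.0 - model.acquisition_bleach_fraction
    keep = 1.0 - protocol.pulse_efficiency
    c0 = simkit.INITIAL_INTENSITY
    mob = np.full(3, (1.0 - model.immobile_fraction) * c0)
    imm = np.full(3, model.immobile_fraction * c0)
    pulses = set(protocol.pulse_frames)
    conc = np.empty((protocol.n_frames, 3))
    for k in range(protocol.n_frames):
        if k > 0:
            for _ in range(substeps):
                k1 = deriv(mob)
                k2 = deriv(mob + 0.5 * dt * k1)
                k3 = deriv(mob + 0.5 * dt * k2)
                k4 = deriv(mob + dt * k3)
                mob = mob + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        mob, imm = mob * q, imm * q
        conc[k] = mob + imm
        if k in pulses:
            mob = mob.copy()
            imm = imm.copy()
            mob[0] *= keep
            imm[0] *= keep
    roi_side = (conc[:, 0] * v[0] + conc[:, 1] * v[1]) / (v[0] + v[1])
    other = conc[:, 2]
    if protocol.roi_compartment == "mother":
        mother, bud = roi_side, other
    else:
        mother, bud = other, roi_side
    if protocol.mode == "frap_single":
        if protocol.roi_compartment == "mother":
            mother = conc[:, 0]
        else:
            bud = conc[:, 0]
    return mother, bud


def random_model_protocol(rng: np.random.Generator) -> tuple[CompartmentModel, BleachProtocol]:
    """A random but physically sensible parameter set for oracle checks."""
    model = CompartmentModel(
        volume_mother=rng.uniform(0.5, 2.0),
        volume_bud=rng.uniform(0.1, 0.8),
        exchange_rate=10 ** rng.uniform(-3, -0.5),
        intra_mixing_rate=10 ** rng.uniform(-1.5, 0.3),
        acquisition_bleach_fraction=rng.uniform(0.0, 0.01),
        immobile_fraction=rng.uniform(0.0, 0.3),
    )
    mode = "flip_repeated" if rng.random() < 0.7 else "frap_single"
    n_frames = int(rng.integers(15, 25))
    if mode == "flip_repeated":
        pulse_frames = tuple(range(n_frames - 1))
    else:
        pulse_frames = (int(rng.integers(0, 3)),)
    protocol = BleachProtocol(
        mode=mode,
        frame_interval=rng.uniform(0.5, 2.0),
        n_frames=n_frames,
        pulse_frames=pulse_frames,
        pulse_efficiency=rng.uniform(0.3, 0.9),
        roi_compartment="mother" if rng.random() < 0.8 else "bud",
        roi_fraction=rng.uniform(0.05, 0.5),
    )
    return model, protocol


def decay_grid_search(
    t: np.ndarray, y: np.ndarray, n_grid: int = 400
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Dense (rate, plateau) grid-search oracle for the constrained decay fit.

    Returns (best_rate, best_plateau, rate_grid, plateau_grid).
    """
    rates = np.logspace(-4, 0, n_grid)
    plateaus = np.linspace(0.0, 100.0, n_grid)
    e = np.exp(-np.outer(rates, t))  # (R, T)
    pred = plateaus[:, None, None] + (100.0 - plateaus[:, None, None]) * e[None, :, :]
    ssr = np.sum((pred - y[None, None, :]) ** 2, axis=2)  # (P, R)
    ip, ir = np.unravel_index(np.argmin(ssr), ssr.shape)
    return float(rates[ir]), float(plateaus[ip]), rates, plateaus
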