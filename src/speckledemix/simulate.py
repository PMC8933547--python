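"""Synthetic speckle-fingerprint data generation.

Physical picture: each point emitter behind a scattering layer produces a
fully developed speckle pattern ("fingerprint") on the camera.  Emitters
that are close to each other produce fingerprints that are shifted copies
of one another (memory effect); as their separation grows the patterns
decorrelate.  A camera frame is a non-negative linear mixture of the
fingerprints with random per-frame illumination weights.

The fingerprint model used here synthesises each pattern as

    w_k = | IFFT2{ A(f) * exp(i [phi0(f) - 2*pi*f.r_k + sigma*psi(f, r_k)]) } |^2

where ``A`` is a circular low-pass aperture (sets the speckle grain size),
``phi0`` is a single random phase screen shared by all emitters, the linear
tilt encodes the emitter position as a translation of the pattern, and
``psi(f, r)`` is a phase perturbation that varies smoothly with emitter
position (built from a grid of independent anchor screens with Gaussian
interpolation weights).  ``sigma`` is calibrated so that the intensity
correlation of two fingerprints drops to ~0.5 at a separation of one
memory-effect range.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

__all__ = [
    "OpticalConfig",
    "EmitterMap",
    "GroundTruth",
    "FrameStack",
    "generate_emitters",
    "synthesize_fingerprints",
    "synthesize_weights",
    "compose_frames",
    "simulate_dataset",
]

# Tags used to derive independent child RNG streams from one master seed.
_TAG_EMITTERS = 101
_TAG_PHASE = 102
_TAG_ANCHORS = 103
_TAG_WEIGHTS = 104
_TAG_NOISE = 105


def _rng(seed: int, tag: int) -> np.random.Generator:
    """Deterministic child generator for a (master seed, purpose tag) pair."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(tag)]))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class OpticalConfig:
    """Parameters of the synthetic optical system.

    Parameters
    ----------
    frame_height, frame_width : int
        Camera frame size in pixels (>= 8).
    grain_size : float
        Mean speckle grain size (approximate FWHM) in pixels, >= 1.
    me_range : float
        Memory-effect radius in pixels: separation at which the
        fingerprint intensity correlation has dropped to ~0.5.  Must
        exceed ``grain_size``.
    noise_photons : float or None
        Expected photon count at the brightest pixel of the stack
        (Poisson scale).  ``None`` disables shot noise.
    read_noise_sigma : float
        Standard deviation of additive Gaussian read noise, in counts.
    seed : int
        Master seed; all randomness downstream derives from it.
    """

    frame_height: int = 96
    frame_width: int = 96
    grain_size: float = 4.0
    me_range: float = 20.0
    noise_photons: float | None = None
    read_noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_height < 8 or self.frame_width < 8:
            raise ValueError("frame dimensions must be >= 8 pixels")
        if self.grain_size < 1:
            raise ValueError("grain_size must be >= 1 pixel")
        if self.me_range <= self.grain_size:
            raise ValueError("me_range must exceed grain_size")
        if self.noise_photons is not None and self.noise_photons <= 0:
            raise ValueError("noise_photons must be positive or None")
        if self.read_noise_sigma < 0:
            raise ValueError("read_noise_sigma must be >= 0")

    @property
    def frame_shape(self) -> tuple[int, int]:
        return (self.frame_height, self.frame_width)


@dataclasses.dataclass(frozen=True)
class EmitterMap:
    """Positions (row, col offsets from the frame centre) and brightness
    of the point emitters making up the hidden object."""

    positions: np.ndarray  # (P, 2) float, sub-pixel (row, col)
    brightness: np.ndarray  # (P,) non-negative

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        bri = np.asarray(self.brightness, dtype=float).ravel()
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 1:
            raise ValueError("positions must be a (P, 2) array with P >= 1")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        if bri.shape[0] != pos.shape[0]:
            raise ValueError("brightness length must match number of positions")
        if np.any(bri < 0):
            raise ValueError("brightness must be non-negative")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "brightness", bri)

    @property
    def count(self) -> int:
        return self.positions.shape[0]

    def pairwise_distances(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d**2).sum(axis=-1))

    def span(self) -> float:
        """Largest pairwise distance between emitters."""
        return float(self.pairwise_distances().max())


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator knows: true fingerprints W (pixels x P),
    true weights H (P x T), the emitter layout and the optical config."""

    fingerprints: np.ndarray  # (H*W, P) non-negative
    weights: np.ndarray  # (P, T) non-negative
    emitter_map: EmitterMap
    config: OpticalConfig

    def __post_init__(self) -> None:
        w = np.asarray(self.fingerprints, dtype=float)
        h = np.asarray(self.weights, dtype=float)
        npix = self.config.frame_height * self.config.frame_width
        if w.shape != (npix, self.emitter_map.count):
            raise ValueError("fingerprints must be (n_pixels, P)")
        if h.ndim != 2 or h.shape[0] != self.emitter_map.count:
            raise ValueError("weights must be (P, T)")
        if np.any(w < 0) or np.any(h < 0):
            raise ValueError("ground truth factors must be non-negative")
        object.__setattr__(self, "fingerprints", w)
        object.__setattr__(self, "weights", h)

    @property
    def n_frames(self) -> int:
        return self.weights.shape[1]

    def fingerprint_image(self, k: int) -> np.ndarray:
        return self.fingerprints[:, k].reshape(self.config.frame_shape)


@dataclasses.dataclass(frozen=True)
class FrameStack:
    """A stack of T non-negative camera frames, shape (T, H, W).

    Pixel coordinates are 0-based (row, col)."""

    frames: np.ndarray

    def __post_init__(self) -> None:
        fr = np.asarray(self.frames, dtype=float)
        if fr.ndim != 3 or fr.shape[0] < 1:
            raise ValueError("frames must be a (T, H, W) array with T >= 1")
        if not np.all(np.isfinite(fr)):
            raise ValueError("frames must be finite")
        if np.any(fr < 0):
            raise ValueError("frames must be non-negative")
        object.__setattr__(self, "frames", fr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def __len__(self) -> int:
        return self.n_frames


# ---------------------------------------------------------------------------
# Emitter layouts
# ---------------------------------------------------------------------------


def generate_emitters(
    n: int,
    fov_radius: float,
    min_separation: float = 0.0,
    layout: str = "random",
    seed: int = 0,
    chain_step: float | None = None,
    max_attempts: int = 20000,
) -> EmitterMap:
    """Place ``n`` emitters inside a disc of radius ``fov_radius``.

    Layouts
    -------
    ``random``
        Rejection sampling with all pairwise distances >= min_separation.
    ``ring``
        Equally spaced on a circle of radius ``fov_radius``.
    ``connected_chain``
        A gently meandering chain with consecutive spacing ``chain_step``
        (required), so that consecutive emitters stay within a caller's
        memory-effect range and the chain spans roughly
        ``(n - 1) * chain_step``.

    Raises if the requested density cannot be realised within
    ``max_attempts`` rejection-sampling attempts.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fov_radius <= 0:
        raise ValueError("fov_radius must be positive")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    rng = _rng(seed, _TAG_EMITTERS)

    if layout == "random":
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < n:
            if attempts >= max_attempts:
                raise RuntimeError(
                    f"could not place {n} emitters with min_separation="
                    f"{min_separation} in fov_radius={fov_radius}"
                )
            attempts += 1
            cand = rng.uniform(-fov_radius, fov_radius, 2)
            if np.hypot(*cand) > fov_radius:
                continue
            if all(np.hypot(*(cand - p)) >= min_separation for p in pts):
                pts.append(cand)
        positions = np.array(pts)
    elif layout == "ring":
        if n == 1:
            positions = np.zeros((1, 2))
        else:
            theta = 2 * np.pi * np.arange(n) / n + rng.uniform(0, 2 * np.pi)
            positions = fov_radius * np.stack([np.sin(theta), np.cos(theta)], axis=1)
            chord = 2 * fov_radius * math.sin(math.pi / n)
            if chord < min_separation:
                raise RuntimeError("ring too small for requested min_separation")
    elif layout == "connected_chain":
        if chain_step is None:
            raise ValueError("connected_chain layout requires chain_step")
        if chain_step <= 0:
            raise ValueError("chain_step must be positive")
        if (n - 1) * chain_step / 2 > fov_radius:
            raise RuntimeError("chain does not fit inside fov_radius")
        for _ in range(max_attempts):
            # straight backbone in a random direction + bounded transverse jitter
            direction = rng.uniform(0, 2 * np.pi)
            u = np.array([math.sin(direction), math.cos(direction)])
            v = np.array([math.cos(direction), -math.sin(direction)])
            jitter = rng.uniform(-0.2 * chain_step, 0.2 * chain_step, n)
            positions = (
                np.arange(n)[:, None] * chain_step * u[None, :]
                + jitter[:, None] * v[None, :]
            )
            positions -= positions.mean(axis=0)
            dists = np.hypot(*(positions[:, None, :] - positions[None, :, :]).T)
            np.fill_diagonal(dists, np.inf)
            if dists.min() >= min_separation and np.all(
                np.hypot(*positions.T) <= fov_radius
            ):
                break
        else:
            raise RuntimeError("could not realise connected_chain layout")
    else:
        raise ValueError(f"unknown layout {layout!r}")

    return EmitterMap(positions=positions, brightness=np.ones(n))


# ---------------------------------------------------------------------------
# Fingerprints
# ---------------------------------------------------------------------------


def _anchor_grid(positions: np.ndarray, spacing: float) -> np.ndarray:
    """Grid of anchor points covering the emitter bounding box plus margin."""
    lo = positions.min(axis=0) - 2 * spacing
    hi = positions.max(axis=0) + 2 * spacing
    rows = np.arange(lo[0], hi[0] + spacing, spacing)
    cols = np.arange(lo[1], hi[1] + spacing, spacing)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1)


def _anchor_weights(pos: np.ndarray, anchors: np.ndarray, width: float) -> np.ndarray:
    """Normalised Gaussian interpolation weights of one position onto anchors."""
    d2 = ((anchors - pos[None, :]) ** 2).sum(axis=1)
    g = np.exp(-d2 / (2 * width**2))
    norm = math.sqrt(float((g**2).sum()))
    if norm == 0:
        raise RuntimeError("emitter too far from anchor grid")
    return g / norm


def synthesize_fingerprints(
    emitters: EmitterMap, config: OpticalConfig
) -> np.ndarray:
    """Generate one speckle fingerprint per emitter.

    Returns the (n_pixels, P) non-negative matrix whose column k is the
    fingerprint of emitter k flattened in row-major order, normalised to
    unit mean and scaled by the emitter brightness.

    Nearby emitters (separation << me_range) get mutually shifted, highly
    correlated patterns; the correlation decays with separation and is
    ~0.5 at ``me_range``.
    """
    if config.grain_size <= 0 or config.me_range <= 0:
        raise ValueError("grain_size and me_range must be positive")
    H, W = config.frame_shape
    P = emitters.count
    pos = emitters.positions

    fr = np.fft.fftfreq(H)[:, None]
    fc = np.fft.fftfreq(W)[None, :]
    f_ap = 0.5 / config.grain_size
    mask = (fr**2 + fc**2) <= f_ap**2

    rng_phase = _rng(config.seed, _TAG_PHASE)
    phi0 = rng_phase.uniform(0.0, 2 * np.pi, (H, W))

    # Position-correlated phase perturbation from anchor screens.  Wide
    # interpolation bumps keep the anchor-weight overlap C high at one
    # me_range, which forces a large calibrated sigma and hence a near-zero
    # correlation floor for far-apart emitters.
    L = float(config.me_range)
    width = 1.5 * L
    anchors = _anchor_grid(pos, spacing=L)
    rng_anch = _rng(config.seed, _TAG_ANCHORS)
    screens = rng_anch.standard_normal((anchors.shape[0], H, W))
    coeff = np.stack([_anchor_weights(p, anchors, width) for p in pos])  # (P, M)

    # Calibrate sigma so that intensity correlation ~0.5 at one me_range:
    # corr = exp(-2 sigma^2 (1 - C)) with C the anchor-weight overlap.
    probes = []
    for p in pos[: min(P, 8)]:
        c0 = _anchor_weights(p, anchors, width)
        for dv in ([L, 0.0], [0.0, L]):
            c1 = _anchor_weights(p + np.asarray(dv), anchors, width)
            probes.append(float(c0 @ c1))
    C_me = float(np.clip(np.mean(probes), 0.0, 0.99))
    sigma = math.sqrt(math.log(2.0) / (2.0 * (1.0 - C_me)))

    out = np.empty((H * W, P))
    for k in range(P):
        tilt = -2 * np.pi * (fr * pos[k, 0] + fc * pos[k, 1])
        psi = np.tensordot(coeff[k], screens, axes=1)
        field = np.fft.ifft2(mask * np.exp(1j * (phi0 + tilt + sigma * psi)))
        w = np.abs(field) ** 2
        w /= w.mean()
        out[:, k] = emitters.brightness[k] * w.ravel()
    return out


# ---------------------------------------------------------------------------
# Illumination weights
# ---------------------------------------------------------------------------


def synthesize_weights(
    P: int,
    T: int,
    model: str = "iid_exponential",
    config: OpticalConfig | None = None,
    emitters: EmitterMap | None = None,
) -> np.ndarray:
    """Draw the (P, T) non-negative illumination weight matrix.

    ``iid_exponential`` draws every weight independently from a unit-mean
    exponential law (fully developed speckle intensity statistics).

    ``speckle_field`` synthesises a fresh 2-D illumination speckle for
    every frame and samples its intensity at the emitter positions, so
    emitters closer than a grain get correlated weights; requires
    ``emitters``.
    """
    if P < 1 or T < 1:
        raise ValueError("P and T must be >= 1")
    if config is None:
        config = OpticalConfig()
    rng = _rng(config.seed, _TAG_WEIGHTS)

    if model == "iid_exponential":
        return rng.exponential(1.0, (P, T))

    if model == "speckle_field":
        if emitters is None or emitters.count != P:
            raise ValueError("speckle_field model requires a matching EmitterMap")
        pos = emitters.positions
        lo = pos.min(axis=0)
        margin = 4 * config.grain_size
        idx = pos - lo[None, :] + margin  # canvas coordinates
        size = int(np.ceil((pos - lo).max() + 2 * margin)) + 1
        size = max(size, 32)
        f1 = np.fft.fftfreq(size)
        f2 = f1[:, None] ** 2 + f1[None, :] ** 2
        fmask = f2 <= (0.5 / config.grain_size) ** 2
        rows = np.clip(np.rint(idx[:, 0]).astype(int), 0, size - 1)
        cols = np.clip(np.rint(idx[:, 1]).astype(int), 0, size - 1)
        out = np.empty((P, T))
        for t in range(T):
            phase = rng.uniform(0.0, 2 * np.pi, (size, size))
            field = np.fft.ifft2(fmask * np.exp(1j * phase))
            inten = np.abs(field) ** 2
            inten /= inten.mean()
            out[:, t] = inten[rows, cols]
        return out

    raise ValueError(f"unknown weight model {model!r}")


# ---------------------------------------------------------------------------
# Frame composition
# ---------------------------------------------------------------------------


def compose_frames(truth: GroundTruth) -> FrameStack:
    """Mix fingerprints and weights into a camera frame stack.

    The noiseless frame t is exactly ``sum_k w_k * h_k(t)``.  If the
    config requests noise, frames are scaled so the brightest pixel
    expects ``noise_photons`` photons, Poisson shot noise is applied,
    then Gaussian read noise is added and negatives are clipped to zero.
    """
    cfg = truth.config
    W = truth.fingerprints
    Hw = truth.weights
    T = truth.n_frames
    noiseless = (W @ Hw).T.reshape(T, cfg.frame_height, cfg.frame_width)

    if cfg.noise_photons is None and cfg.read_noise_sigma == 0:
        return FrameStack(frames=noiseless)

    rng = _rng(cfg.seed, _TAG_NOISE)
    frames = noiseless
    if cfg.noise_photons is not None:
        peak = noiseless.max()
        if peak <= 0:
            raise ValueError("cannot scale an all-zero stack to photon counts")
        scale = cfg.noise_photons / peak
        frames = rng.poisson(noiseless * scale).astype(float) / scale
    if cfg.read_noise_sigma > 0:
        frames = frames + rng.normal(0.0, cfg.read_noise_sigma, frames.shape)
    return FrameStack(frames=np.clip(frames, 0.0, None))


def simulate_dataset(
    emitters: EmitterMap,
    config: OpticalConfig,
    n_frames: int,
    weight_model: str = "iid_exponential",
) -> tuple[GroundTruth, FrameStack]:
    """Convenience wrapper: fingerprints + weights + frames in one call."""
    fingerprints = synthesize_fingerprints(emitters, config)
    weights = synthesize_weights(
        emitters.count, n_frames, model=weight_model, config=config, emitters=emitters
    )
    truth = GroundTruth(
        fingerprints=fingerprints,
        weights=weights,
        emitter_map=emitters,
        config=config,
    )
    return truth, compose_frames(truth)
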