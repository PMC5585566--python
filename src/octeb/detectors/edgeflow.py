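"""EdgeFlow boundary detection.

EdgeFlow casts boundary finding as vector-field propagation instead of
local gradient peak-picking.  At each pixel s and candidate direction
theta, an edge energy E(s, theta) and a predictive-coding probability
P(s, theta) are computed per image attribute (intensity and Gabor
texture) and pooled with weights omega(a):

    E(s, theta) = sum_a E_a(s, theta) * omega(a),   sum_a omega(a) = 1
    P(s, theta) = sum_a P_a(s, theta) * omega(a)

The flow direction Theta(s) maximizes the half-plane sum of P, and the
EdgeFlow vector is the complex sum

    F(s) = sum_{Theta <= theta < Theta + pi} E(s, theta) * exp(j theta),

whose magnitude is the edge energy and phase the flow direction.  The
vectors are propagated iteratively toward their pointing direction; in
the stable state, boundaries appear where two opposite flows meet.

Per attribute, E_a is the magnitude of the directional first-derivative-
of-Gaussian response at scale sigma, and P_a is the ratio of predictive
coding errors looking along theta versus theta + pi, with the prediction
taken at an offset of 4*sigma.  The texture attribute replaces the
intensity image with the energy images of a small Gabor filter bank.

Angles are measured from the +column axis toward the +row axis, so the
unit vector of theta is (drow, dcol) = (sin theta, cos theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import gabor

from ._common import hysteresis, normalize_response

__all__ = [
    "EdgeFlowParams",
    "edgeflow_energy",
    "edgeflow_direction",
    "edgeflow_vector",
    "propagate_flow",
    "edgeflow_detect",
]


@dataclass(frozen=True)
class EdgeFlowParams:
    """Scale, direction grid, attribute weights, and texture bank.

    ``n_directions`` must be even so that theta and theta + pi are both on
    the grid.  ``w_intensity`` and ``w_texture`` are the pooling weights
    omega(a) and must sum to 1 (equal weighting by default).  The Gabor
    bank is ``gabor_orientations`` evenly spaced orientations at each
    frequency in ``gabor_frequencies``, with kernel width tied to sigma.
    """

    sigma: float = 3.0
    n_directions: int = 8
    w_intensity: float = 0.5
    w_texture: float = 0.5
    max_iterations: int = 30
    t_low: float = 0.005
    t_high: float = 0.1
    gabor_frequencies: tuple[float, ...] = (0.1, 0.2)
    gabor_orientations: int = 4

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.n_directions < 4 or self.n_directions % 2:
            raise ValueError("n_directions must be an even integer >= 4")
        if self.w_intensity < 0 or self.w_texture < 0:
            raise ValueError("attribute weights must be >= 0")
        if abs(self.w_intensity + self.w_texture - 1.0) > 1e-9:
            raise ValueError(
                f"attribute weights must sum to 1, got "
                f"{self.w_intensity} + {self.w_texture}"
            )
        if not 0 <= self.t_low < self.t_high:
            raise ValueError(
                f"need 0 <= t_low < t_high, got {self.t_low} and {self.t_high}"
            )
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @property
    def angles(self) -> np.ndarray:
        """The discretized directions theta_k = 2 pi k / n over [0, 2 pi)."""
        return 2.0 * np.pi * np.arange(self.n_directions) / self.n_directions


def _shift_sample(arr: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Sample arr at (r + drow, c + dcol) with edge replication."""
    rows = np.clip(np.arange(arr.shape[0]) + drow, 0, arr.shape[0] - 1)
    cols = np.clip(np.arange(arr.shape[1]) + dcol, 0, arr.shape[1] - 1)
    return arr[np.ix_(rows, cols)]


def _attribute_energy(
    channels: list[np.ndarray], sigma: float, angles: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Directional energies and prediction errors of one attribute.

    Energy: magnitude of the directional derivative-of-Gaussian response,
    summed over the attribute's channels.  Prediction error: magnitude of
    the difference between the smoothed value and its value offset by
    d = 4*sigma along theta, summed over channels.
    """
    n = len(angles)
    shape = channels[0].shape
    energy = np.zeros((n,) + shape)
    error = np.zeros((n,) + shape)
    d = 4.0 * sigma
    for ch in channels:
        ch = np.asarray(ch, dtype=float)
        g_row = ndi.gaussian_filter(ch, sigma, order=(1, 0), mode="nearest")
        g_col = ndi.gaussian_filter(ch, sigma, order=(0, 1), mode="nearest")
        smoothed = ndi.gaussian_filter(ch, sigma, mode="nearest")
        for k, theta in enumerate(angles):
            energy[k] += np.abs(g_col * np.cos(theta) + g_row * np.sin(theta))
            drow = int(round(d * np.sin(theta)))
            dcol = int(round(d * np.cos(theta)))
            error[k] += np.abs(_shift_sample(smoothed, drow, dcol) - smoothed)
    return energy, error


def _error_probability(error: np.ndarray) -> np.ndarray:
    """P(s, theta) = Err(s, theta) / (Err(s, theta) + Err(s, theta + pi)).

    Where the denominator vanishes (no change either way), P is 0.5, so
    P(s, theta) + P(s, theta + pi) = 1 always holds.
    """
    n = error.shape[0]
    opposite = np.roll(error, -n // 2, axis=0)
    denom = error + opposite
    prob = np.full_like(error, 0.5)
    np.divide(error, denom, out=prob, where=denom > 1e-300)
    return prob


def _texture_channels(image: np.ndarray, params: EdgeFlowParams) -> list[np.ndarray]:
    """Gabor-bank energy images used as the texture attribute's channels."""
    channels = []
    for freq in params.gabor_frequencies:
        for i in range(params.gabor_orientations):
            theta = np.pi * i / params.gabor_orientations
            real, imag = gabor(
                image, frequency=freq, theta=theta,
                sigma_x=params.sigma, sigma_y=params.sigma, mode="nearest",
            )
            channels.append(np.hypot(real, imag))
    return channels


def edgeflow_energy(
    image: np.ndarray, params: EdgeFlowParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled edge energy E(s, theta) and probability P(s, theta).

    Returns two arrays of shape (n_directions, H, W).  The intensity and
    texture attributes are always both computed and pooled with omega, so
    a zero weight contributes exactly nothing.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    params = params or EdgeFlowParams()
    angles = params.angles
    e_int, err_int = _attribute_energy([image], params.sigma, angles)
    e_tex, err_tex = _attribute_energy(_texture_channels(image, params), params.sigma, angles)
    energy = params.w_intensity * e_int + params.w_texture * e_tex
    prob = (
        params.w_intensity * _error_probability(err_int)
        + params.w_texture * _error_probability(err_tex)
    )
    return energy, prob


def edgeflow_direction(prob: np.ndarray) -> np.ndarray:
    """Flow direction index: argmax_theta of the half-plane sum of P.

    The half plane [theta_k, theta_k + pi) covers n/2 consecutive grid
    directions; ties break toward the smallest angle.  Returns the integer
    grid index of Theta(s) per pixel.
    """
    n = prob.shape[0]
    half = n // 2
    sums = np.empty_like(prob)
    for k in range(n):
        idx = (np.arange(k, k + half)) % n
        sums[k] = prob[idx].sum(axis=0)
    return np.argmax(sums, axis=0)


def edgeflow_vector(energy: np.ndarray, theta_idx: np.ndarray) -> np.ndarray:
    """EdgeFlow vector F(s): half-plane sum of E(s, theta) exp(j theta).

    Returns a complex array; real part is the column component, imaginary
    part the row component of the flow.
    """
    n = energy.shape[0]
    half = n // 2
    angles = 2.0 * np.pi * np.arange(n) / n
    phasors = energy * np.exp(1j * angles)[:, None, None]
    flows = np.empty((n,) + energy.shape[1:], dtype=complex)
    for k in range(n):
        idx = (np.arange(k, k + half)) % n
        flows[k] = phasors[idx].sum(axis=0)
    return np.take_along_axis(flows, theta_idx[None], axis=0)[0]


# 8-neighbor offsets (drow, dcol) by 45-degree sector of the flow angle.
_FLOW_OFFSETS = np.array(
    [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]
)


def propagate_flow(
    flow: np.ndarray, max_iterations: int = 30
) -> tuple[np.ndarray, int, bool]:
    """Propagate EdgeFlow vectors to their stable state.

    Each pixel transmits its vector to the 8-neighbor nearest its flow
    direction, but only if that neighbor's current flow direction differs
    from its own by less than 90 degrees; otherwise the vector stays put.
    Iterates until no vector moves or ``max_iterations`` is reached.

    Returns ``(stable_flow, n_iterations, converged)``.
    """
    flow = np.asarray(flow, dtype=complex)
    height, width = flow.shape
    rr, cc = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    for iteration in range(1, max_iterations + 1):
        sector = np.round(np.angle(flow) / (np.pi / 4.0)).astype(int) % 8
        drow = _FLOW_OFFSETS[sector, 0]
        dcol = _FLOW_OFFSETS[sector, 1]
        nr, nc = rr + drow, cc + dcol
        inbounds = (nr >= 0) & (nr < height) & (nc >= 0) & (nc < width)
        neighbor = np.zeros_like(flow)
        neighbor[inbounds] = flow[nr[inbounds], nc[inbounds]]
        # dot product > 0  <=>  directions differ by < 90 degrees
        dot = flow.real * neighbor.real + flow.imag * neighbor.imag
        transmit = inbounds & (dot > 0) & (np.abs(flow) > 0)
        new = np.zeros_like(flow)
        np.add.at(new, (nr[transmit], nc[transmit]), flow[transmit])
        stay = ~transmit
        new[stay] += flow[stay]
        if np.array_equal(new, flow):
            return flow, iteration, True
        flow = new
    return flow, max_iterations, False


def _opposing_strength(flow: np.ndarray) -> np.ndarray:
    """Edge strength where neighboring stable vectors point at each other.

    For each 4-neighbor pair whose vectors subtend more than 90 degrees
    and both point across the shared border, the strength (sum of the two
    magnitudes) is credited to the pixel with the larger energy.
    """
    strength = np.zeros(flow.shape)

    def mark(f_a, f_b, comp_a, comp_b, sl_a, sl_b):
        dot = f_a.real * f_b.real + f_a.imag * f_b.imag
        meet = (dot < 0) & (comp_a > 0) & (comp_b < 0)
        pair = np.abs(f_a) + np.abs(f_b)
        win_a = meet & (np.abs(f_a) >= np.abs(f_b))
        win_b = meet & ~win_a
        view_a, view_b = strength[sl_a], strength[sl_b]
        view_a[win_a] = np.maximum(view_a[win_a], pair[win_a])
        view_b[win_b] = np.maximum(view_b[win_b], pair[win_b])

    # vertical pairs: p at (r, c), q at (r + 1, c); border crossed along +row
    f_a, f_b = flow[:-1], flow[1:]
    mark(f_a, f_b, f_a.imag, f_b.imag, np.s_[:-1], np.s_[1:])
    # horizontal pairs: p at (r, c), q at (r, c + 1); border crossed along +col
    f_a, f_b = flow[:, :-1], flow[:, 1:]
    mark(f_a, f_b, f_a.real, f_b.real, np.s_[:, :-1], np.s_[:, 1:])
    return strength


def edgeflow_detect(image: np.ndarray, params: EdgeFlowParams | None = None) -> np.ndarray:
    """Full EdgeFlow pipeline; returns a boolean edge map.

    Energy/probability fields -> flow direction -> EdgeFlow vector ->
    propagation to the stable state -> opposing-flow boundary strengths,
    normalized to max 1 and cleaned by hysteresis.
    """
    params = params or EdgeFlowParams()
    energy, prob = edgeflow_energy(image, params)
    theta_idx = edgeflow_direction(prob)
    flow = edgeflow_vector(energy, theta_idx)
    stable, _, _ = propagate_flow(flow, params.max_iterations)
    strength = normalize_response(_opposing_strength(stable))
    return hysteresis(strength, params.t_low, params.t_high)
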