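"""Four-layer competitive hierarchy with topological Gaussian connectivity.

Each layer is a 2-D grid of neurons.  A neuron receives a fixed number of
afferent synapses sampled, without replacement, from a Gaussian centred on
its topologically corresponding location in the preceding layer (the layer-1
afferents additionally sample a Gabor channel uniformly).  The Gaussian
scale is set so that the configured radius captures ~67% of the connection
probability mass, which produces receptive fields that grow through the
hierarchy until fourth-layer neurons see the whole retina.

The forward pass per layer is: linear activation (weighted sum of afferent
rates), soft lateral inhibition (convolution of the activation map with a
centre-minus-Gaussian-surround filter), then sigmoid contrast enhancement
whose threshold is set each presentation to a fixed percentile of the
layer's inhibited activations — giving direct control of firing sparseness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import expit

__all__ = [
    "LayerConfig",
    "SynapticTopology",
    "LayerState",
    "Network",
    "baseline_layer_configs",
    "large_retina_layer_configs",
    "sample_topology",
    "compute_activations",
    "inhibition_kernel",
    "lateral_inhibition",
    "sigmoid_transfer",
    "sparseness",
    "gaussian_scale_for_radius",
]

CAPTURE_FRACTION = 0.67  # probability mass inside the stated afferent radius


@dataclass(frozen=True)
class LayerConfig:
    """Per-layer structural and competition parameters.

    ``radius`` is measured in presynaptic grid units.  ``sigma`` and
    ``delta`` are the width and contrast of the lateral-inhibition filter;
    ``percentile``/``slope`` parameterize the sigmoid transfer (threshold at
    the given percentile of inhibited activations, slope beta).
    """

    grid: int
    n_afferents: int
    radius: float
    sigma: float
    delta: float
    percentile: float = 95.0
    slope: float = 40.0

    @property
    def n_neurons(self) -> int:
        return self.grid * self.grid


def baseline_layer_configs() -> list[LayerConfig]:
    """128x128x32 retina set-up: 32x32 layers, 100 afferents per neuron."""
    return [
        LayerConfig(grid=32, n_afferents=100, radius=6.0, sigma=1.38, delta=1.5, percentile=95.0, slope=190.0),
        LayerConfig(grid=32, n_afferents=100, radius=6.0, sigma=2.7, delta=1.5, percentile=95.0, slope=40.0),
        LayerConfig(grid=32, n_afferents=100, radius=9.0, sigma=4.0, delta=1.6, percentile=95.0, slope=75.0),
        LayerConfig(grid=32, n_afferents=100, radius=12.0, sigma=6.0, delta=1.4, percentile=95.0, slope=26.0),
    ]


def large_retina_layer_configs() -> list[LayerConfig]:
    """256x256x64 retina set-up: 64x64 first layer, 200 afferents, doubled radii."""
    return [
        LayerConfig(grid=64, n_afferents=200, radius=24.0, sigma=1.38, delta=1.5, percentile=95.0, slope=190.0),
        LayerConfig(grid=32, n_afferents=200, radius=24.0, sigma=2.7, delta=1.5, percentile=95.0, slope=40.0),
        LayerConfig(grid=32, n_afferents=200, radius=36.0, sigma=4.0, delta=1.6, percentile=95.0, slope=75.0),
        LayerConfig(grid=32, n_afferents=200, radius=48.0, sigma=6.0, delta=1.4, percentile=95.0, slope=26.0),
    ]


@dataclass
class SynapticTopology:
    """Afferent index lists and weights for every neuron of one layer.

    ``pre_shape`` is the presynaptic array shape — (H, W, C) for the retina
    or (G, G) for a neuronal layer; ``pre_index`` holds flat indices into
    that array, shape (n_post, n_afferents); ``weights`` is the matching
    weight matrix, each row kept at unit Euclidean length.
    """

    pre_shape: tuple[int, ...]
    post_grid: int
    pre_index: np.ndarray
    weights: np.ndarray

    @property
    def n_afferents(self) -> int:
        return self.pre_index.shape[1]

    def pre_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Spatial (row, col) coordinates of every afferent."""
        if len(self.pre_shape) == 3:
            h, w, c = self.pre_shape
            spatial = self.pre_index // c
            return spatial // w, spatial % w
        h, w = self.pre_shape
        return self.pre_index // w, self.pre_index % w


def gaussian_scale_for_radius(radius: float, capture: float = CAPTURE_FRACTION) -> float:
    """Scale s of the 2-D isotropic Gaussian with P(|offset| <= radius) = capture."""
    return radius / math.sqrt(-2.0 * math.log(1.0 - capture))


def sample_topology(pre_shape: tuple[int, ...], post_grid: int, n_afferents: int,
                    radius: float, rng: np.random.Generator,
                    init_weights: bool = True) -> SynapticTopology:
    """Sample afferents for every neuron of a layer.

    Offsets are drawn from the 2-D Gaussian matched to ``radius``, rounded
    to the presynaptic lattice and redrawn when they fall outside the grid
    or duplicate an already-sampled synapse (sampling without replacement).
    When the presynaptic array has channels, each afferent also draws its
    channel uniformly.  Initial weights are uniform positive random numbers
    normalized to unit row length.
    """
    if len(pre_shape) == 3:
        pre_h, pre_w, pre_c = pre_shape
    else:
        pre_h, pre_w = pre_shape
        pre_c = 0
    n_pre = pre_h * pre_w * max(pre_c, 1)
    if n_afferents > n_pre:
        raise ValueError(f"cannot sample {n_afferents} afferents from {n_pre} units")
    scale = gaussian_scale_for_radius(radius)
    ratio_h = pre_h / post_grid
    ratio_w = pre_w / post_grid
    pre_index = np.empty((post_grid * post_grid, n_afferents), dtype=np.int64)
    for i in range(post_grid):
        for j in range(post_grid):
            cy = (i + 0.5) * ratio_h - 0.5
            cx = (j + 0.5) * ratio_w - 0.5
            chosen: list[int] = []
            seen: set[int] = set()
            attempts = 0
            while len(chosen) < n_afferents:
                attempts += 1
                if attempts > 200:
                    raise ValueError(
                        f"could not place {n_afferents} afferents within the "
                        f"truncation window around ({i},{j})"
                    )
                m = 2 * (n_afferents - len(chosen)) + 8
                off = rng.normal(0.0, scale, size=(m, 2))
                ry = np.rint(cy + off[:, 0]).astype(np.int64)
                rx = np.rint(cx + off[:, 1]).astype(np.int64)
                ok = (ry >= 0) & (ry < pre_h) & (rx >= 0) & (rx < pre_w)
                ry, rx = ry[ok], rx[ok]
                if pre_c:
                    ch = rng.integers(0, pre_c, size=ry.shape[0])
                    flat = (ry * pre_w + rx) * pre_c + ch
                else:
                    flat = ry * pre_w + rx
                for f in flat:
                    f = int(f)
                    if f not in seen:
                        seen.add(f)
                        chosen.append(f)
                        if len(chosen) == n_afferents:
                            break
            pre_index[i * post_grid + j] = chosen
    if init_weights:
        w = rng.uniform(0.0, 1.0, size=pre_index.shape)
        w /= np.linalg.norm(w, axis=1, keepdims=True)
    else:
        w = np.full(pre_index.shape, 1.0 / math.sqrt(n_afferents))
    return SynapticTopology(pre_shape=tuple(pre_shape), post_grid=post_grid,
                            pre_index=pre_index, weights=w)


def compute_activations(rates_pre: np.ndarray, topology: SynapticTopology) -> np.ndarray:
    """Linear activation h_i = sum_j w_ij x_j over each neuron's afferents."""
    x = np.asarray(rates_pre).ravel()
    return np.einsum("ij,ij->i", topology.weights, x[topology.pre_index])


def inhibition_kernel(sigma: float, delta: float) -> np.ndarray:
    """Lateral-inhibition filter: negative Gaussian surround, centre weight
    chosen so the filter sums to 1 (a uniform activation map passes
    unchanged); truncated at +-ceil(3 sigma)."""
    extent = int(math.ceil(3.0 * sigma))
    aa, bb = np.mgrid[-extent:extent + 1, -extent:extent + 1].astype(np.float64)
    k = -delta * np.exp(-(aa ** 2 + bb ** 2) / sigma ** 2)
    k[extent, extent] = 0.0
    k[extent, extent] = 1.0 - k.sum()
    return k


def lateral_inhibition(activations: np.ndarray, sigma: float, delta: float,
                       kernel: np.ndarray | None = None,
                       denom: np.ndarray | None = None) -> np.ndarray:
    """Convolve the 2-D activation map with the inhibition filter.

    Near the grid edge the filter is clipped; the result is renormalized by
    the in-grid filter mass so a uniform map is preserved there too.
    """
    if kernel is None:
        kernel = inhibition_kernel(sigma, delta)
    out = signal.fftconvolve(activations, kernel, mode="same")
    if denom is None:
        denom = signal.fftconvolve(np.ones_like(activations), kernel, mode="same")
    return out / denom


def sigmoid_transfer(inhibited: np.ndarray, percentile: float, slope: float) -> np.ndarray:
    """Firing rates y = 1 / (1 + exp(-2 beta (h' - alpha))).

    The threshold alpha is recomputed every presentation as the given
    percentile of the layer's current inhibited activations, so roughly
    (100 - percentile)% of neurons fire above 0.5.
    """
    alpha = np.percentile(inhibited, percentile)
    return expit(2.0 * slope * (inhibited - alpha))


def sparseness(rates: np.ndarray) -> float:
    """Population sparseness a = (mean y)^2 / mean(y^2).

    Equals the active fraction for binary rates and 1 for a uniform
    population.  Undefined (raises) when every rate is zero.
    """
    y = np.asarray(rates, dtype=np.float64).ravel()
    if np.any(y < 0):
        raise ValueError("rates must be non-negative")
    denom = np.mean(y * y)
    if denom == 0.0:
        raise ValueError("sparseness undefined for all-zero rates")
    return float(np.mean(y) ** 2 / denom)


@dataclass
class LayerState:
    """Snapshot of one layer during a presentation."""

    activations: np.ndarray
    inhibited: np.ndarray
    rates: np.ndarray


@dataclass
class Network:
    """The full hierarchy: retina shape, layer configs and their synapses."""

    retina_shape: tuple[int, int, int]
    configs: list[LayerConfig]
    topologies: list[SynapticTopology]
    _kernels: list[np.ndarray] = field(default_factory=list, repr=False)
    _denoms: list[np.ndarray] = field(default_factory=list, repr=False)

    @classmethod
    def build(cls, configs: list[LayerConfig], retina_shape: tuple[int, int, int],
              rng: np.random.Generator) -> "Network":
        topologies = []
        pre_shape: tuple[int, ...] = retina_shape
        for cfg in configs:
            topologies.append(sample_topology(pre_shape, cfg.grid, cfg.n_afferents,
                                              cfg.radius, rng))
            pre_shape = (cfg.grid, cfg.grid)
        return cls(retina_shape=retina_shape, configs=configs, topologies=topologies)

    def _inhibition_terms(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        if not self._kernels:
            for cfg in self.configs:
                kern = inhibition_kernel(cfg.sigma, cfg.delta)
                ones = np.ones((cfg.grid, cfg.grid))
                self._kernels.append(kern)
                self._denoms.append(signal.fftconvolve(ones, kern, mode="same"))
        return self._kernels[k], self._denoms[k]

    def layer_step(self, k: int, rates_pre: np.ndarray) -> LayerState:
        """Forward one layer: activation, inhibition, sigmoid."""
        cfg = self.configs[k]
        h = compute_activations(rates_pre, self.topologies[k]).reshape(cfg.grid, cfg.grid)
        kern, denom = self._inhibition_terms(k)
        h_inh = lateral_inhibition(h, cfg.sigma, cfg.delta, kernel=kern, denom=denom)
        y = sigmoid_transfer(h_inh, cfg.percentile, cfg.slope)
        return LayerState(activations=h, inhibited=h_inh, rates=y)

    def forward(self, retina_response: np.ndarray, upto: int | None = None) -> list[LayerState]:
        """Deterministic forward pass; returns the state of every layer."""
        x = np.asarray(retina_response).ravel()
        states: list[LayerState] = []
        n_layers = len(self.configs) if upto is None else upto + 1
        for k in range(n_layers):
            st = self.layer_step(k, x)
            states.append(st)
            x = st.rates.ravel()
        return states

    def output_rates(self, retina_response: np.ndarray) -> np.ndarray:
        return self.forward(retina_response)[-1].rates

    def effective_field(self, layer: int, neuron: int) -> np.ndarray:
        """Boolean retina-pixel mask of all inputs that can reach a neuron.

        Traces afferent index sets down the hierarchy; used to verify that
        receptive fields grow with depth and span the retina at the top.
        """
        active = np.zeros(self.configs[layer].n_neurons, dtype=bool)
        active[neuron] = True
        for k in range(layer, 0, -1):
            topo = self.topologies[k]
            pre = np.zeros(self.configs[k - 1].n_neurons, dtype=bool)
            pre[np.unique(topo.pre_index[active])] = True
            active = pre
        topo = self.topologies[0]
        h, w, c = self.retina_shape
        mask = np.zeros(h * w, dtype=bool)
        spatial = np.unique(topo.pre_index[active] // c)
        mask[spatial] = True
        return mask.reshape(h, w)
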