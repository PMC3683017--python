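"""Information-theoretic read-out of the output layer.

Two complementary measures quantify whether output cells encode the
hand-relative target location invariantly of retinal position:

*Single-cell stimulus-specific information.*  For one cell with binned
responses R over all stimulus x retinal-location test presentations,

    I(s, R) = sum_r P(r | s) log2( P(r | s) / P(r) ),

and the cell's reported value is max_s I(s, R).  The measure is bounded by
log2(n_stimuli) — 1.58 bits for three hand-object configurations — and the
bound is attained exactly when the cell responds to a single configuration
at every retinal location and never otherwise.

*Multiple-cell information.*  The stimulus is decoded from the ensemble
response vector of the highest-information cells (five per stimulus); the
mutual information of the resulting (actual, decoded)-stimulus probability
table, as a function of ensemble size, measures whether the population
represents *all* configurations.  Decoding is nearest-class-mean with
leave-one-out cross-validation over retinal locations; a Gaussian
(diagonal-covariance Bayes) decoder is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from visnet_hand.network import Network

__all__ = [
    "ResponseTable",
    "InfoReport",
    "compute_response_table",
    "single_cell_information",
    "analyse_responses",
    "rank_cells",
    "select_ensemble",
    "multiple_cell_information",
    "mutual_information_from_table",
]

AT_MAX_TOL = 1e-6  # float-safe margin for counting cells at the information cap


@dataclass
class ResponseTable:
    """Output-layer firing rates for every test presentation.

    ``rates`` has shape (n_cells, n_stimuli, n_locations): one deterministic
    forward pass per (configuration, retinal shift) pair on the frozen
    network.
    """

    rates: np.ndarray
    stimulus_labels: list[str]

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def n_stimuli(self) -> int:
        return self.rates.shape[1]

    @property
    def n_locations(self) -> int:
        return self.rates.shape[2]


@dataclass
class InfoReport:
    """Per-cell information values plus the derived summaries."""

    info_per_stimulus: np.ndarray  # (n_cells, n_stimuli) bits
    cell_info: np.ndarray          # (n_cells,) max over stimuli
    preferred_stimulus: np.ndarray  # (n_cells,) argmax (lowest index on ties)
    max_info: float                # log2(n_stimuli)
    stimulus_labels: list[str]

    @property
    def n_cells_at_max(self) -> int:
        return int(np.sum(self.cell_info >= self.max_info - AT_MAX_TOL))

    def at_max_mask(self) -> np.ndarray:
        return self.cell_info >= self.max_info - AT_MAX_TOL


def compute_response_table(network: Network, retina_sequences: list[list[np.ndarray]],
                           labels: list[str] | None = None) -> ResponseTable:
    """Evaluate the frozen network on every (stimulus, location) frame."""
    n_stim = len(retina_sequences)
    n_loc = len(retina_sequences[0])
    n_cells = network.configs[-1].n_neurons
    rates = np.empty((n_cells, n_stim, n_loc))
    for s, seq in enumerate(retina_sequences):
        for l, frame in enumerate(seq):
            rates[:, s, l] = network.output_rates(frame).ravel()
    if labels is None:
        labels = [f"stim{s}" for s in range(n_stim)]
    return ResponseTable(rates=rates, stimulus_labels=labels)


def _bin_responses(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width binning of one cell's responses over its observed range."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.searchsorted(edges, values, side="right") - 1
    return np.clip(idx, 0, n_bins - 1)


def single_cell_information(responses: np.ndarray, n_bins: int = 3) -> np.ndarray:
    """Stimulus-specific information of one cell, in bits per stimulus.

    ``responses`` has shape (n_stimuli, n_locations); all presentations are
    treated as equiprobable.  Returns I(s, R) for every stimulus s; the
    cell's single-cell information is the maximum entry.
    """
    responses = np.asarray(responses, dtype=np.float64)
    if responses.ndim != 2:
        raise ValueError("expected a (n_stimuli, n_locations) response matrix")
    n_stim, n_loc = responses.shape
    if n_loc < 1:
        raise ValueError("every stimulus needs at least one response")
    binned = _bin_responses(responses.ravel(), n_bins).reshape(responses.shape)
    n_total = n_stim * n_loc
    info = np.zeros(n_stim)
    counts_r = np.bincount(binned.ravel(), minlength=n_bins).astype(np.float64)
    p_r = counts_r / n_total
    for s in range(n_stim):
        counts_rs = np.bincount(binned[s], minlength=n_bins).astype(np.float64)
        p_rs = counts_rs / n_loc
        nz = p_rs > 0
        info[s] = float(np.sum(p_rs[nz] * np.log2(p_rs[nz] / p_r[nz])))
    return info


def analyse_responses(table: ResponseTable, n_bins: int = 3) -> InfoReport:
    """Single-cell information analysis of the whole output layer."""
    n_cells, n_stim, _ = table.rates.shape
    info = np.empty((n_cells, n_stim))
    for c in range(n_cells):
        info[c] = single_cell_information(table.rates[c], n_bins=n_bins)
    cell_info = info.max(axis=1)
    preferred = info.argmax(axis=1)
    return InfoReport(info_per_stimulus=info, cell_info=cell_info,
                      preferred_stimulus=preferred,
                      max_info=float(np.log2(n_stim)),
                      stimulus_labels=table.stimulus_labels)


def rank_cells(report: InfoReport) -> np.ndarray:
    """Cell indices in descending information order (stable on ties)."""
    order = np.argsort(-report.cell_info, kind="stable")
    return order


def select_ensemble(report: InfoReport, n_per_stimulus: int = 5) -> np.ndarray:
    """The decoding ensemble: per stimulus, the cells with the most
    stimulus-specific information about it.

    Each cell is first offered to its preferred (best) stimulus, so a cell
    that ranks highly for two stimuli is assigned once — to its best — and
    the other stimulus fills with its next-best cell.  A stimulus whose
    preferred pool runs dry (as happens when cohorts merge) fills the rest
    of its quota from the remaining unassigned cells ranked by their
    information about that stimulus.  The returned order interleaves
    stimuli so every prefix of the ensemble covers all of them.
    """
    n_cells, n_stim = report.info_per_stimulus.shape
    if n_cells < n_per_stimulus * n_stim:
        raise ValueError(
            f"need {n_per_stimulus * n_stim} cells, have only {n_cells}")
    per_stim: list[list[int]] = []
    taken = np.zeros(n_cells, dtype=bool)
    for s in range(n_stim):
        pool = np.flatnonzero(report.preferred_stimulus == s)
        order = pool[np.argsort(-report.info_per_stimulus[pool, s], kind="stable")]
        chosen = [int(c) for c in order[:n_per_stimulus]]
        taken[chosen] = True
        per_stim.append(chosen)
    for s in range(n_stim):
        if len(per_stim[s]) < n_per_stimulus:
            backfill = np.argsort(-report.info_per_stimulus[:, s], kind="stable")
            for c in backfill:
                if not taken[c]:
                    per_stim[s].append(int(c))
                    taken[c] = True
                    if len(per_stim[s]) == n_per_stimulus:
                        break
    ensemble = np.empty(n_per_stimulus * n_stim, dtype=np.int64)
    for k in range(n_per_stimulus):
        for s in range(n_stim):
            ensemble[k * n_stim + s] = per_stim[s][k]
    return ensemble


def mutual_information_from_table(joint: np.ndarray) -> float:
    """Mutual information (bits) of a joint (actual, decoded) probability table."""
    p = np.asarray(joint, dtype=np.float64)
    total = p.sum()
    if total <= 0:
        raise ValueError("probability table must have positive mass")
    p = p / total
    ps = p.sum(axis=1, keepdims=True)
    pd = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (ps @ pd)[nz])))


def _decode_loo(vectors: np.ndarray, decoder: str) -> np.ndarray:
    """Leave-one-out decoding of (n_stim, n_loc, n_cells) response vectors."""
    n_stim, n_loc, _ = vectors.shape
    decoded = np.empty((n_stim, n_loc), dtype=np.int64)
    for s in range(n_stim):
        for l in range(n_loc):
            means = np.stack([
                np.mean(np.delete(vectors[t], l, axis=0), axis=0) if t == s
                else vectors[t].mean(axis=0)
                for t in range(n_stim)
            ])
            v = vectors[s, l]
            if decoder == "nearest_mean":
                d = np.linalg.norm(means - v, axis=1)
                decoded[s, l] = int(np.argmin(d))
            elif decoder == "gaussian":
                var = np.stack([
                    np.var(np.delete(vectors[t], l, axis=0), axis=0) if t == s
                    else vectors[t].var(axis=0)
                    for t in range(n_stim)
                ]) + 1e-6
                ll = -0.5 * np.sum((means - v) ** 2 / var + np.log(var), axis=1)
                decoded[s, l] = int(np.argmax(ll))
            else:
                raise ValueError(f"unknown decoder {decoder!r}")
    return decoded


def multiple_cell_information(table: ResponseTable, ensemble: np.ndarray,
                              sizes: list[int] | None = None,
                              decoder: str = "nearest_mean") -> tuple[np.ndarray, np.ndarray]:
    """Mutual information between actual and decoded stimulus vs ensemble size.

    For every prefix of the ensemble, each presentation's stimulus is
    decoded from the ensemble response vector (class means estimated with
    the tested presentation held out), the (s, s') confusion table is
    accumulated over all presentations, and its mutual information is
    evaluated.  Returns (sizes, bits).
    """
    ensemble = np.asarray(ensemble, dtype=np.int64)
    if ensemble.size == 0:
        raise ValueError("ensemble must be non-empty")
    if sizes is None:
        sizes = list(range(1, ensemble.size + 1))
    n_stim, n_loc = table.n_stimuli, table.n_locations
    bits = np.empty(len(sizes))
    for i, m in enumerate(sizes):
        cells = ensemble[:m]
        vectors = np.transpose(table.rates[cells], (1, 2, 0))  # (stim, loc, cells)
        decoded = _decode_loo(vectors, decoder)
        joint = np.zeros((n_stim, n_stim))
        for s in range(n_stim):
            for l in range(n_loc):
                joint[s, decoded[s, l]] += 1.0
        bits[i] = mutual_information_from_table(joint)
    return np.asarray(sizes), bits
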