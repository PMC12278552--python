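"""Within-herd social contact networks.

Each herd gets a simple random graph whose degrees are iid Poisson with
mean 30, truncated above at the 99% Poisson quantile (43 contacts) —
the contact counts reported for positioning-sensor networks in ~100-cow
free-stall herds.  Graphs realize the drawn degree sequence exactly
(edge-switching uniform sampling via igraph).  Directed variants split
each cow's contacts roughly half/half into incoming and outgoing arcs
(caps 22 / 21); an arc ``j -> i`` means cow j's indirect effects enter
cow i's phenotype.  Optional per-dyad contact intensities are gamma
distributed (shape 1, rate 2), optionally standardized to mean 1, and an
analysis-side copy can carry additive Gaussian measurement noise.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, replace

import igraph as ig
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContactNetwork",
    "sample_degree_sequence",
    "split_directed_degrees",
    "build_undirected_network",
    "build_directed_network",
    "sample_intensities",
    "add_intensity_noise",
    "simulate_contact_networks",
    "truncated_poisson_mean",
]

DEFAULT_MEAN_CONTACTS = 30
DEFAULT_MAX_CONTACTS = 43  # 99% quantile of Poisson(30)
DEFAULT_MAX_IN = 22
DEFAULT_MAX_OUT = 21


@dataclass
class ContactNetwork:
    """Edge list of one or many herd networks.

    ``edges`` columns: herd, source, target, f_true, f_analysis.
    Undirected dyads are stored once with source < target and a single
    shared intensity used symmetrically in both phenotypes.
    """

    directed: bool
    edges: pd.DataFrame
    cow_herd: pd.Series  # cow id -> herd id, covers isolated cows too

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def incoming_counts(self) -> pd.Series:
        """Number of contacts contributing to each cow's phenotype."""
        counts = pd.Series(0, index=self.cow_herd.index, dtype=int)
        if self.directed:
            got = self.edges["target"].value_counts()
        else:
            got = pd.concat([self.edges["source"], self.edges["target"]]).value_counts()
        counts.loc[got.index] += got.astype(int)
        return counts


def truncated_poisson_mean(mean: float, max_value: int) -> float:
    """Mean of a Poisson(mean) truncated above at ``max_value`` (by direct summation)."""
    k = np.arange(0, max_value + 1)
    p = stats.poisson.pmf(k, mean)
    return float((k * p).sum() / p.sum())


def _igraph_seeded(seed: int):
    """Seed igraph's generator (it uses Python's random module)."""
    ig.set_random_number_generator(_random.Random(seed))


def sample_degree_sequence(
    herd_size: int,
    mean: float = DEFAULT_MEAN_CONTACTS,
    max_contacts: int = DEFAULT_MAX_CONTACTS,
    seed=None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Iid truncated-Poisson degrees, repaired to an even, graphical sum.

    Values above ``max_contacts`` are redrawn (truncation preserves the
    conditional distribution).  If the sum is odd or the sequence is not
    graphical, one uniformly chosen cow's degree is resampled; bounded at
    100 attempts.
    """
    if max_contacts >= herd_size:
        raise ValueError("max_contacts must be smaller than the herd size")
    rng = rng if rng is not None else np.random.default_rng(seed)

    def draw(size: int) -> np.ndarray:
        d = rng.poisson(mean, size)
        while (over := d > max_contacts).any():
            d[over] = rng.poisson(mean, int(over.sum()))
        return d

    degrees = draw(herd_size)
    for _ in range(100):
        if degrees.sum() % 2 == 0 and ig.is_graphical(degrees.tolist()):
            return degrees
        degrees[rng.integers(herd_size)] = draw(1)[0]
    raise RuntimeError(
        f"could not repair degree sequence (sum {degrees.sum()}, "
        f"herd size {herd_size}, mean {mean}, max {max_contacts})"
    )


def build_undirected_network(
    degrees: np.ndarray, seed=None, rng: np.random.Generator | None = None
) -> list[tuple[int, int]]:
    """Simple undirected graph realizing ``degrees`` exactly (0-based edge list)."""
    degrees = np.asarray(degrees)
    if degrees.sum() % 2 != 0 or not ig.is_graphical(degrees.tolist()):
        raise ValueError("degree sequence is not graphical with an even sum")
    rng = rng if rng is not None else np.random.default_rng(seed)
    _igraph_seeded(int(rng.integers(2**31 - 1)))
    g = ig.Graph.Degree_Sequence(degrees.tolist(), method="edge_switching_simple")
    return [tuple(sorted(e)) for e in g.get_edgelist()]


def build_directed_network(
    in_degrees: np.ndarray,
    out_degrees: np.ndarray,
    seed=None,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int]]:
    """Simple directed graph realizing both sequences; edges are (source, target)."""
    in_degrees = np.asarray(in_degrees)
    out_degrees = np.asarray(out_degrees)
    if in_degrees.sum() != out_degrees.sum():
        raise ValueError("in- and out-degree totals must match")
    rng = rng if rng is not None else np.random.default_rng(seed)
    _igraph_seeded(int(rng.integers(2**31 - 1)))
    g = ig.Graph.Degree_Sequence(
        out_degrees.tolist(), in_degrees.tolist(), method="edge_switching_simple"
    )
    return g.get_edgelist()


def split_directed_degrees(
    total_degrees: np.ndarray,
    max_in: int = DEFAULT_MAX_IN,
    max_out: int = DEFAULT_MAX_OUT,
    rng: np.random.Generator | None = None,
    seed=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split total contact counts into in/out degrees.

    Each cow's total is split by a balanced binomial(n_i, 1/2), clipped so
    in <= max_in and out <= max_out, then in/out totals are equalized by
    unit transfers on randomly chosen cows (the totals can only balance
    when the grand total is even, which the degree repair guarantees).
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    total = np.asarray(total_degrees)
    if total.max(initial=0) > max_in + max_out:
        raise ValueError("a total degree exceeds max_in + max_out")
    if total.sum() % 2 != 0:
        raise ValueError("total degree sum must be even to balance in/out totals")
    d_in = rng.binomial(total, 0.5)
    d_in = np.clip(d_in, np.maximum(0, total - max_out), np.minimum(max_in, total))
    d_out = total - d_in
    target = total.sum() // 2
    for _ in range(10 * total.size + 100):
        excess = d_in.sum() - target
        if excess == 0:
            break
        if excess > 0:  # move a unit from in to out somewhere
            ok = (d_in > np.maximum(0, total - max_out)) & (d_out < max_out)
            i = rng.choice(np.flatnonzero(ok))
            d_in[i] -= 1
            d_out[i] += 1
        else:
            ok = (d_out > np.maximum(0, total - max_in)) & (d_in < max_in)
            i = rng.choice(np.flatnonzero(ok))
            d_in[i] += 1
            d_out[i] -= 1
    else:
        raise RuntimeError("could not balance in/out degree totals")
    return d_in, d_out


def simulate_contact_networks(
    pedigree: pd.DataFrame,
    mean_contacts: float = DEFAULT_MEAN_CONTACTS,
    max_contacts: int = DEFAULT_MAX_CONTACTS,
    directed: bool = False,
    rng: np.random.Generator | None = None,
    seed=None,
) -> ContactNetwork:
    """One contact network per herd for all phenotyped cows in ``pedigree``."""
    rng = rng if rng is not None else np.random.default_rng(seed)
    cows = pedigree[pedigree["role"] == "cow"]
    cow_herd = pd.Series(cows["herd"].to_numpy(), index=cows["animal"].to_numpy())
    frames = []
    for herd, ids in cows.groupby("herd")["animal"]:
        ids = ids.to_numpy()
        degrees = sample_degree_sequence(ids.size, mean_contacts, max_contacts, rng=rng)
        if directed:
            d_in, d_out = split_directed_degrees(degrees, rng=rng)
            edges = build_directed_network(d_in, d_out, rng=rng)
        else:
            edges = build_undirected_network(degrees, rng=rng)
        if edges:
            src, tgt = map(np.array, zip(*edges))
            frames.append(
                pd.DataFrame(
                    {"herd": herd, "source": ids[src], "target": ids[tgt]}
                )
            )
    edges = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["herd", "source", "target"])
    )
    edges["f_true"] = 1.0
    edges["f_analysis"] = 1.0
    return ContactNetwork(directed=directed, edges=edges, cow_herd=cow_herd)


def sample_intensities(
    network: ContactNetwork,
    shape: float = 1.0,
    rate: float = 2.0,
    standardize: bool = True,
    rng: np.random.Generator | None = None,
    seed=None,
) -> ContactNetwork:
    """Attach iid gamma(shape, rate) intensities, one per stored edge.

    With ``standardize`` the draws are divided by their mean shape/rate, so
    the intensities have mean 1 (and variance 1 for shape=1, rate=2).
    Undirected dyads carry one shared intensity for both usage directions.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges to attach intensities to")
    rng = rng if rng is not None else np.random.default_rng(seed)
    f = rng.gamma(shape, 1.0 / rate, network.n_edges)
    if standardize:
        f = f / (shape / rate)
    edges = network.edges.assign(f_true=f, f_analysis=f)
    return replace(network, edges=edges)


def add_intensity_noise(
    network: ContactNetwork,
    noise_var: float,
    rng: np.random.Generator | None = None,
    seed=None,
) -> ContactNetwork:
    """Analysis-side intensities = true intensities + N(0, noise_var) noise.

    The simulation-side ``f_true`` is untouched; noisy values may be
    negative and are used as-is.
    """
    if noise_var < 0:
        raise ValueError("noise variance must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    noisy = network.edges["f_true"].to_numpy() + rng.normal(
        0.0, np.sqrt(noise_var), network.n_edges
    )
    edges = network.edges.assign(f_analysis=noisy)
    return replace(network, edges=edges)
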