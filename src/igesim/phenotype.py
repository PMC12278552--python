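"""Phenotype construction from genetic, environmental, herd and network inputs.

A cow's milk yield is its herd effect plus its own direct genetic and
environmental effect, plus the intensity-weighted sum of the indirect
genetic and indirect environmental effects of its incoming contacts:

    y_i = herd_i + a_D,i + sum_j f_ij (a_I,j + e_I,j) + e_D,i

For undirected networks every contact is incoming; for directed networks
only arcs pointing at the cow contribute.  With intensities off, f = 1.
Construction is fully deterministic given its inputs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .network import ContactNetwork

__all__ = ["simulate_phenotypes", "realized_variance_report"]


def _receiving_edges(network: ContactNetwork) -> pd.DataFrame:
    """Edge list expanded to (recipient, partner, f) rows.

    Undirected dyads contribute twice (once per endpoint) with the shared
    intensity; directed arcs contribute only to their target.
    """
    e = network.edges
    if network.directed:
        return pd.DataFrame(
            {"recipient": e["target"], "partner": e["source"], "f": e["f_true"]}
        )
    fwd = pd.DataFrame({"recipient": e["target"], "partner": e["source"], "f": e["f_true"]})
    bwd = pd.DataFrame({"recipient": e["source"], "partner": e["target"], "f": e["f_true"]})
    return pd.concat([fwd, bwd], ignore_index=True)


def simulate_phenotypes(
    bvs: pd.DataFrame,
    env: pd.DataFrame,
    herds: pd.DataFrame,
    network: ContactNetwork,
    use_intensity: bool = False,
) -> pd.DataFrame:
    """Phenotypes for every cow in the network's herds.

    Parameters
    ----------
    bvs : breeding-value table with columns animal, a_D, a_I.
    env : environmental effects with columns animal, e_D, e_I (cows only).
    herds : herd effects with columns herd, herd_effect.
    network : contact network; its ``cow_herd`` index defines the cows.
    use_intensity : weight partner effects by the simulated intensities
        (otherwise every contact has weight 1).

    Returns
    -------
    DataFrame with columns cow, herd, y, n_contacts (incoming when directed).
    """
    cow_ids = network.cow_herd.index.to_numpy()
    bv = bvs.set_index("animal")
    ev = env.set_index("animal")
    missing = set(cow_ids) - set(bv.index)
    if missing:
        raise ValueError(f"cow {sorted(missing)[0]} missing from the breeding-value table")
    missing = set(cow_ids) - set(ev.index)
    if missing:
        raise ValueError(f"cow {sorted(missing)[0]} missing from the environmental table")

    recv = _receiving_edges(network)
    bad = set(recv["partner"]) - set(cow_ids)
    if bad:
        raise ValueError(f"contact references non-phenotyped animal {sorted(bad)[0]}")
    w = recv["f"].to_numpy() if use_intensity else 1.0
    partner_sum = (
        bv.loc[recv["partner"], "a_I"].to_numpy()
        + ev.loc[recv["partner"], "e_I"].to_numpy()
    ) * w
    social = pd.Series(partner_sum).groupby(recv["recipient"].to_numpy()).sum()
    social = social.reindex(cow_ids, fill_value=0.0).to_numpy()

    herd_of = network.cow_herd.to_numpy()
    herd_effect = herds.set_index("herd").loc[herd_of, "herd_effect"].to_numpy()
    y = (
        herd_effect
        + bv.loc[cow_ids, "a_D"].to_numpy()
        + social
        + ev.loc[cow_ids, "e_D"].to_numpy()
    )
    return pd.DataFrame(
        {
            "cow": cow_ids,
            "herd": herd_of,
            "y": y,
            "n_contacts": network.incoming_counts().loc[cow_ids].to_numpy(),
        }
    )


def realized_variance_report(phenos: pd.DataFrame, herds: pd.DataFrame) -> dict[str, float]:
    """Realized within-herd phenotypic variance, for validation against the
    configured variance budget.

    Returns the pooled within-herd variance of y (herd effects removed by
    centring within herd) plus the mean contact count actually realized.
    """
    if (phenos.groupby("herd")["y"].size() < 2).any():
        raise ValueError("every herd needs at least 2 cows")
    centred = phenos["y"] - phenos.groupby("herd")["y"].transform("mean")
    n = len(phenos)
    n_herds = phenos["herd"].nunique()
    pooled = float((centred**2).sum() / (n - n_herds))
    return {
        "within_herd_variance": pooled,
        "mean_contacts": float(phenos["n_contacts"].mean()),
        "n_cows": float(n),
        "n_herds": float(n_herds),
    }
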