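"""Molecular dating from the pedigree mutation rate.

The per-parent count regression evaluated at the mean wild reproduction
ages, corrected for false positives/negatives and callability, gives the
per-generation rate; dividing by the generation time gives the yearly rate
used to convert branch lengths (substitutions per site) into divergence
times.  Speciation predates molecular divergence by the ancestral
coalescent lag 2 * Ne * G, with Ne from the Watterson relation pi = 4 Ne mu.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .parental import ParentAgeModel


@dataclass
class DatingInputs:
    """Everything needed to date a set of nodes."""

    model: ParentAgeModel
    beta: float
    alpha: float
    callable_sites: float
    generation_time: float
    age_maternal: float
    age_paternal: float
    pi: Optional[float] = None
    count_ci: Optional[tuple[float, float]] = None  # CI of the predicted count


@dataclass
class NodeDate:
    name: str
    branch_length: float
    t_divergence: float
    t_divergence_ci: Optional[tuple[float, float]]
    ne_ancestor: Optional[float]
    t_speciation: Optional[float]


def effective_population_size(pi: float, mu_per_generation: float) -> float:
    """Watterson relation: Ne = pi / (4 mu)."""
    if mu_per_generation <= 0:
        raise ValueError("mutation rate must be positive")
    return pi / (4.0 * mu_per_generation)


def generation_rate(
    model: ParentAgeModel,
    age_maternal: float,
    age_paternal: float,
    beta: float,
    alpha: float,
    callable_sites: float,
) -> float:
    """Per-generation rate implied by the count model at the given ages."""
    count = model.predict_total(age_maternal, age_paternal)
    return count * (1.0 - beta) / ((1.0 - alpha) * 2.0 * callable_sites)


def yearly_rate(
    model: ParentAgeModel,
    age_maternal: float,
    age_paternal: float,
    beta: float,
    alpha: float,
    callable_sites: float,
    generation_time: float,
    count_ci: Optional[tuple[float, float]] = None,
) -> tuple[float, Optional[tuple[float, float]]]:
    """Yearly rate: predicted count x (1-beta) / ((1-alpha) * 2 * C * G).

    The optional ``count_ci`` (confidence interval of the predicted total
    count, from the regression) is propagated through the same linear
    correction to give a CI on the yearly rate.
    """
    if generation_time <= 0:
        raise ValueError("generation time must be positive")
    mu = generation_rate(model, age_maternal, age_paternal, beta, alpha,
                         callable_sites) / generation_time
    ci = None
    if count_ci is not None:
        scale = (1.0 - beta) / ((1.0 - alpha) * 2.0 * callable_sites * generation_time)
        ci = (count_ci[0] * scale, count_ci[1] * scale)
    return mu, ci


def divergence_time(
    branch_length: float,
    mu_yearly: float,
    mu_yearly_ci: Optional[tuple[float, float]] = None,
) -> tuple[float, Optional[tuple[float, float]]]:
    """Divergence time (years): branch length / yearly rate.

    The CI follows the monotone transform: (branch/hi, branch/lo).
    """
    if mu_yearly <= 0:
        raise ValueError("yearly rate must be positive")
    t = branch_length / mu_yearly
    ci = None
    if mu_yearly_ci is not None:
        lo, hi = mu_yearly_ci
        ci = (branch_length / hi, branch_length / lo)
    return t, ci


def speciation_time(t_divergence: float, ne_ancestor: float, generation_time: float) -> float:
    """Speciation time: T_divergence - 2 * Ne_ancestor * G, floored at zero."""
    t = t_divergence - 2.0 * ne_ancestor * generation_time
    if t < 0:
        warnings.warn(
            "ancestral coalescent lag exceeds the divergence time; "
            "speciation time floored at 0"
        )
        return 0.0
    return t


def date_tree(
    nodes: Sequence[tuple[str, float, Optional[float]]] | pd.DataFrame,
    mu_yearly: float,
    generation_time: float,
    mu_yearly_ci: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Date a list of (name, branch_length, Ne_ancestor-or-None) nodes.

    Returns a table with divergence times (and CIs when a rate CI is
    given) and speciation times where the ancestral Ne is known.
    """
    if isinstance(nodes, pd.DataFrame):
        records = [
            (
                row["name"],
                float(row["branch_length"]),
                None if pd.isna(row.get("ne_ancestor")) else float(row["ne_ancestor"]),
            )
            for _, row in nodes.iterrows()
        ]
    else:
        records = list(nodes)
    rows = []
    for name, branch, ne in records:
        if branch is None or pd.isna(branch):
            raise ValueError(f"node {name}: missing branch length")
        t_d, ci = divergence_time(branch, mu_yearly, mu_yearly_ci)
        t_s = speciation_time(t_d, ne, generation_time) if ne is not None else None
        rows.append(
            {
                "name": name,
                "branch_length": branch,
                "t_divergence": t_d,
                "t_divergence_low": ci[0] if ci else None,
                "t_divergence_high": ci[1] if ci else None,
                "ne_ancestor": ne,
                "t_speciation": t_s,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "branch_length", "t_divergence", "t_divergence_low",
            "t_divergence_high", "ne_ancestor", "t_speciation",
        ],
    )
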