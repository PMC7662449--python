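"""Summaries of per-animal composition estimates."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import GBCEstimate

__all__ = ["summarize_gbc", "adjust_mixed_subpopulation"]


def summarize_gbc(estimates: list[GBCEstimate]) -> pd.DataFrame:
    """Per-breed mean and sample SD of composition across animals.

    Single-estimate input yields SD 0 by convention (n = 1 is reported
    so the convention is visible).
    """
    if not estimates:
        raise ValueError("need at least one estimate")
    breeds = estimates[0].breeds
    for est in estimates[1:]:
        if est.breeds != breeds:
            raise ValueError(
                f"inconsistent breed sets: {est.breeds} vs {breeds}"
            )
    comp = np.vstack([e.composition for e in estimates])
    n = comp.shape[0]
    sd = comp.std(axis=0, ddof=1) if n > 1 else np.zeros(len(breeds))
    return pd.DataFrame(
        {"breed": breeds, "mean": comp.mean(axis=0), "sd": sd, "n": n}
    )


def adjust_mixed_subpopulation(
    overall_mean: float, sub_mean: float, sub_fraction: float
) -> float:
    """Mean composition of the remainder when a population mixes two
    subgroups: solve overall = frac * sub + (1 - frac) * rest for rest.

    Used, e.g., to back out the composition of non-backcross animals
    from a registry sample known to contain a fraction of backcrosses
    with a pedigree-expected composition.
    """
    if not (0.0 <= sub_fraction < 1.0):
        raise ValueError("subgroup fraction must lie in [0, 1)")
    return (overall_mean - sub_mean * sub_fraction) / (1.0 - sub_fraction)
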