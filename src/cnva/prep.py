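"""Climate stack preparation: crop, ensemble, variable selection, scaling.

Variable selection mirrors the common collinearity filter on bioclimatic
stacks: Pearson correlations are computed over background cells and
variables are greedily eliminated until no pair exceeds the threshold
(default |r| > 0.7).  Standardization scales each variable by the
background mean and SD of the *current* stack; future stacks reuse the
current frame so that climate departures are expressed in current-
climate SD units rather than being biased toward zero.
"""

from __future__ import annotations

import warnings

import numpy as np

from .stack import ClimateStack, StandardizedStack

__all__ = [
    "crop_to_study_area",
    "ensemble_mean",
    "select_variables",
    "standardize",
]


def crop_to_study_area(
    stack: ClimateStack, bounds: tuple[float, float, float, float]
) -> ClimateStack:
    """Clip a stack to ``(west, south, east, north)`` bounds."""
    sub_grid, rs, cs = stack.grid.crop(bounds)
    return ClimateStack(
        grid=sub_grid,
        variables=list(stack.variables),
        values=stack.values[:, rs, cs],
        mask=stack.mask[rs, cs],
        label=stack.label,
    )


def ensemble_mean(stacks: list[ClimateStack]) -> ClimateStack:
    """Cellwise mean across model members (e.g. a GCM ensemble)."""
    if not stacks:
        raise ValueError("ensemble_mean requires at least one stack")
    first = stacks[0]
    for k, s in enumerate(stacks[1:], start=2):
        if not first.same_grid(s) or s.variables != first.variables:
            raise ValueError(
                f"ensemble member {k} ({s.label!r}) does not share the grid "
                f"and variables of member 1 ({first.label!r})"
            )
    return ClimateStack(
        grid=first.grid,
        variables=list(first.variables),
        values=np.mean([s.values for s in stacks], axis=0),
        mask=first.mask,
        label=first.label,
    )


def select_variables(stack: ClimateStack, r_threshold: float = 0.7) -> list[str]:
    """Greedy collinearity filter over background-cell Pearson correlations.

    While any pair of variables has |r| > ``r_threshold``, drop the
    variable with the most offending partners; ties are broken by larger
    mean |r| against the remaining set, then by later list position.
    Zero-variance variables are dropped up front with a warning.
    """
    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must lie in (0, 1)")
    if stack.n_vars < 2:
        raise ValueError("variable selection needs at least 2 variables")
    Z = stack.background_matrix()
    names = list(stack.variables)

    sd = Z.std(axis=0)
    constant = [names[j] for j in range(len(names)) if sd[j] == 0]
    if constant:
        warnings.warn(
            f"dropping constant (zero-variance) variables: {constant}", stacklevel=2
        )
        keep = [j for j in range(len(names)) if sd[j] > 0]
        Z = Z[:, keep]
        names = [names[j] for j in keep]

    active = list(range(len(names)))
    R = np.corrcoef(Z, rowvar=False)
    while True:
        sub = np.abs(R[np.ix_(active, active)])
        np.fill_diagonal(sub, 0.0)
        offending = (sub > r_threshold).sum(axis=1)
        if offending.max(initial=0) == 0:
            break
        worst = offending.max()
        cand = [i for i in range(len(active)) if offending[i] == worst]
        if len(cand) > 1:
            mean_r = sub.mean(axis=1)
            top = max(mean_r[i] for i in cand)
            cand = [i for i in cand if mean_r[i] == top]
        drop = cand[-1]  # later list position
        active.pop(drop)
    return [names[i] for i in active]


def standardize(
    stack: ClimateStack, reference: StandardizedStack | None = None
) -> StandardizedStack:
    """Scale variables to the background mean/SD frame.

    Without a reference, the frame is the stack's own background mean and
    SD (the current-climate convention); with a reference (used for
    future stacks), its ``mu``/``sigma`` are reused so both stacks live
    in one frame.
    """
    if reference is None:
        Z = stack.background_matrix()
        mu = Z.mean(axis=0)
        sigma = Z.std(axis=0)
    else:
        if reference.variables != stack.variables:
            raise ValueError("reference frame has different variables")
        mu, sigma = reference.mu, reference.sigma
    zero = [stack.variables[j] for j in range(stack.n_vars) if sigma[j] == 0]
    if zero:
        raise ValueError(f"zero background SD for variables: {zero}")
    values = (stack.values - mu[:, None, None]) / sigma[:, None, None]
    return StandardizedStack(
        grid=stack.grid,
        variables=list(stack.variables),
        values=values,
        mask=stack.mask,
        label=stack.label,
        mu=mu,
        sigma=sigma,
    )
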