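"""GBLUP-GA weighting: partitioned fits, the tau weight, weighted matrices.

The prior and residual marker sets each get their own relationship
matrices (G1/D1, G2/D2).  Two *separate* REML fits — one per matrix set,
each with the full fixed-effect and permanent-environment structure —
yield the partition genetic variances, and the prior set's share of total
genetic variance

    tau = (sGa1 + sGd1) / (sGa1 + sGd1 + sGa2 + sGd2)

becomes the convex-combination weight for the trait-specific matrix
Gt = tau*G1 + (1-tau)*G2 (and Dt likewise when dominance is modelled).
Separate fits (rather than one joint fit with both matrix sets) match the
distinct permanent-environment/residual estimates the motivating analyses
report per matrix set; a joint fit is available via ``joint=True``.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

from .grm import RelationshipMatrix, combine_matrices
from .mixed_model import (
    DesignSet,
    ModelSpec,
    RemlOptions,
    VarianceComponents,
    reml_estimate,
)

__all__ = [
    "PartitionVariances",
    "fit_partition_models",
    "compute_tau",
    "build_weighted_set",
]


@dataclasses.dataclass
class PartitionVariances:
    sigma_Ga1_2: float
    sigma_Gd1_2: float
    sigma_Ga2_2: float
    sigma_Gd2_2: float
    tau: float
    fit_prior: VarianceComponents | None = None
    fit_residual: VarianceComponents | None = None

    @property
    def converged(self) -> bool:
        fits = [f for f in (self.fit_prior, self.fit_residual) if f is not None]
        return all(f.converged for f in fits)


def compute_tau(
    sigma_Ga1_2: float,
    sigma_Gd1_2: float,
    sigma_Ga2_2: float,
    sigma_Gd2_2: float,
) -> float:
    """Prior-set share of total genetic variance.

    Floor-pinned components enter at their (tiny) floor values.  If every
    component is exactly zero the share is undefined; 0.5 is returned with
    a warning (an uninformative prior).
    """
    for v in (sigma_Ga1_2, sigma_Gd1_2, sigma_Ga2_2, sigma_Gd2_2):
        if v < 0:
            raise ValueError("genetic variances must be non-negative")
    num = sigma_Ga1_2 + sigma_Gd1_2
    den = num + sigma_Ga2_2 + sigma_Gd2_2
    if den == 0.0:
        warnings.warn("all genetic variances are zero; tau defaults to 0.5")
        return 0.5
    return num / den


def _joint_partition_fit(design, G1, D1, G2, D2, spec, options):
    """One REML fit with both matrix sets as separate random effects."""
    import numpy as np

    from .mixed_model import reml_components

    ids = design.individual_ids
    names = ["prior_additive", "residual_additive"]
    A_mats = [G1.align(ids), G2.align(ids)]
    with_dom = spec.include_dominance and D1 is not None and D2 is not None
    if with_dom:
        names += ["prior_dominance", "residual_dominance"]
        A_mats += [D1.align(ids), D2.align(ids)]
    if spec.include_permanent_env:
        names.append("perm_env")
        A_mats.append(np.eye(len(ids)))
    out, ll, converged, it, se, floor = reml_components(design, names, A_mats, options)

    def vc(a_key, d_key):
        return VarianceComponents(
            sigma_a2=out[a_key],
            sigma_d2=out.get(d_key, 0.0),
            sigma_p2=out.get("perm_env", 0.0),
            sigma_e2=out["residual"],
            loglik=ll,
            converged=converged,
            n_iterations=it,
            floor=floor,
        )

    return (
        vc("prior_additive", "prior_dominance"),
        vc("residual_additive", "residual_dominance"),
    )


def fit_partition_models(
    design: DesignSet,
    G1: RelationshipMatrix,
    D1: RelationshipMatrix | None,
    G2: RelationshipMatrix,
    D2: RelationshipMatrix | None,
    spec: ModelSpec | None = None,
    options: RemlOptions | None = None,
    joint: bool = False,
) -> PartitionVariances:
    """Estimate the partition genetic variances and the tau weight.

    Matrices must be built on identical individual sets.  The default is
    two separate single-matrix-set fits; ``joint=True`` instead places both
    matrix sets in one model (the original BLUP|GA formulation), in which
    case the two reported VarianceComponents share their
    permanent-environment and residual estimates.  Non-convergence of
    either fit is propagated as a warning (tau is still computed).
    """
    if G1.individual_ids != G2.individual_ids:
        raise ValueError("G1 and G2 index different individuals")
    spec = spec or design.spec
    if joint:
        fit1, fit2 = _joint_partition_fit(design, G1, D1, G2, D2, spec, options)
    else:
        fit1 = reml_estimate(design, G1, D1, spec, options)
        fit2 = reml_estimate(design, G2, D2, spec, options)
    with_dom = spec.include_dominance
    tau = compute_tau(
        fit1.sigma_a2,
        fit1.sigma_d2 if with_dom else 0.0,
        fit2.sigma_a2,
        fit2.sigma_d2 if with_dom else 0.0,
    )
    pv = PartitionVariances(
        sigma_Ga1_2=fit1.sigma_a2,
        sigma_Gd1_2=fit1.sigma_d2 if with_dom else 0.0,
        sigma_Ga2_2=fit2.sigma_a2,
        sigma_Gd2_2=fit2.sigma_d2 if with_dom else 0.0,
        tau=tau,
        fit_prior=fit1,
        fit_residual=fit2,
    )
    if not pv.converged:
        warnings.warn("a partition REML fit did not converge; tau is flagged")
    return pv


def build_weighted_set(
    G1: RelationshipMatrix,
    G2: RelationshipMatrix,
    D1: RelationshipMatrix | None,
    D2: RelationshipMatrix | None,
    tau: float,
) -> tuple[RelationshipMatrix, RelationshipMatrix | None]:
    """Gt = tau*G1 + (1-tau)*G2, and Dt likewise when dominance is present."""
    Gt = combine_matrices(G1, G2, tau)
    Dt = combine_matrices(D1, D2, tau) if (D1 is not None and D2 is not None) else None
    return Gt, Dt
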