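"""Tunable parameters of the censored network estimation pipeline."""

from __future__ import annotations

import dataclasses


@dataclasses.dataclass
class CNEConfig:
    """Configuration shared by the density, imputation and glasso stages.

    Attributes
    ----------
    tail_factor : float
        The rectangular sample space of an event pair extends to
        ``tail_factor * max(observed time)`` on each axis, leaving room beyond
        the largest observation for the redistributed censored tail mass.
    max_depth : int
        Maximum number of binary splits of the partition recursion; depth 8
        corresponds to a 256 x 256 dyadic resolution.
    min_count : float
        Stop splitting a region once its (fractional) sample count N(A) drops
        below this value.
    min_samples : int
        Minimum number of samples required to fit a pair density.
    grid_size, grid_ratio : int, float
        The penalty path holds ``grid_size`` log-spaced values from
        ``rho_max = max |off-diagonal covariance|`` down to
        ``grid_ratio * rho_max``.
    glasso_tol, glasso_max_iter : float, int
        Outer convergence tolerance (max absolute change of the working
        covariance) and iteration cap of the block-coordinate solver.
    zero_tol : float
        An edge is "present" when ``|theta_ij| > zero_tol``.
    penalize_diagonal : bool
        Whether the L1 penalty also applies to the precision diagonal.  The
        default (False) is the common graphical-lasso convention.
    cv_folds : int
        Folds for cross-validated penalty selection.
    mc_samples : int
        When > 0, conditional tail expectations are approximated by Monte
        Carlo with this many draws instead of the exact closed form.
    seed : int
        Seed for the Monte Carlo path and fold shuffling.
    """

    tail_factor: float = 1.5
    max_depth: int = 8
    min_count: float = 5.0
    min_samples: int = 10
    grid_size: int = 50
    grid_ratio: float = 1e-3
    glasso_tol: float = 1e-7
    glasso_max_iter: int = 200
    zero_tol: float = 1e-8
    penalize_diagonal: bool = False
    cv_folds: int = 5
    mc_samples: int = 0
    seed: int = 0
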