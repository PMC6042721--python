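"""Synthetic networks, covariances and data for the recovery study.

The study design: a ground-truth binary "solution" network combines a
second-order band (every node linked to its one- and two-step neighbours
along the ROI ordering, mimicking the diagonal structure of cortical
networks) with independent Bernoulli extra links among the remaining pairs.
Two standard configurations are used throughout: the semi-sparse S1
(p_extra = 0.1) and the sparse S2 (p_extra = 0.05), both at K = 68 ROIs.

A solution network S becomes a covariance matrix by multiplying its linked
off-diagonals by a positive constant and setting the diagonal by an
eigenvalue-shift rule (offdiag_const * |lambda_min(S)| + 1), which
guarantees positive definiteness; data are then N i.i.d. draws from
MVN(0, Omega). Each estimator's output is scored against S over the strict
upper triangle.

The off-diagonal constants are the one quantity the study design leaves
free; the defaults below were calibrated once (see ``docs/methods.md``) so
that MNL sensitivity at N = 100 sits near its reference operating point,
and are then frozen across all sample sizes and experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import linalg

from ._validation import check_adjacency
from .comparators import glasso_network, ppc_network, score_network
from .mnl import MNLNetwork

__all__ = [
    "S1_P_EXTRA",
    "S2_P_EXTRA",
    "S1_OFFDIAG",
    "S2_OFFDIAG",
    "NetworkSpec",
    "StudyConfig",
    "generate_solution_network",
    "network_to_covariance",
    "sample_data",
    "run_simulation_study",
    "simulate_cohort",
]

# Bernoulli extra-link probabilities of the two study configurations.
S1_P_EXTRA = 0.10
S2_P_EXTRA = 0.05

# Calibrated linked-covariance constants (see module docstring).
S1_OFFDIAG = 6.0
S2_OFFDIAG = 6.0


def generate_solution_network(K: int = 68, p_extra: float = 0.1, seed: int = 0) -> np.ndarray:
    """Second-order band network plus Bernoulli(p_extra) extra links.

    Entries with |j - k| in {1, 2} are always linked; every remaining
    upper-triangle pair is linked independently with probability p_extra.
    """
    if K < 3:
        raise ValueError("need K >= 3 for a second-order band")
    if not 0.0 <= p_extra < 1.0:
        raise ValueError(f"p_extra must lie in [0, 1), got {p_extra}")
    rng = np.random.default_rng(seed)
    S = np.zeros((K, K))
    for offset in (1, 2):
        idx = np.arange(K - offset)
        S[idx, idx + offset] = 1.0
    iu = np.triu_indices(K, k=3)
    S[iu] = rng.random(len(iu[0])) < p_extra
    S += S.T
    return S


def network_to_covariance(
    S, offdiag_const: float = 0.3, diag_const: float | None = None
) -> np.ndarray:
    """Covariance with the network's support: Omega = offdiag_const * S + diag.

    By default the diagonal is ``offdiag_const * |lambda_min(S)| + 1``, an
    eigenvalue shift that guarantees positive definiteness for any network
    (Omega's spectrum is offdiag_const * (lambda(S) - lambda_min(S)) + 1 > 0)
    while allowing linked correlations up to ~1/|lambda_min(S)| — a
    diagonal-dominance rule based on the maximum degree caps them far lower
    and leaves too little signal to recover anything. A user-supplied
    ``diag_const`` is accepted but the result must still pass a Cholesky
    check.
    """
    S = check_adjacency(S, name="S")
    if offdiag_const <= 0:
        raise ValueError("offdiag_const must be positive")
    if diag_const is None:
        lam_min = float(np.linalg.eigvalsh(S)[0])
        diag_const = offdiag_const * max(-lam_min, 0.0) + 1.0
    if diag_const <= 0:
        raise ValueError("diag_const must be positive")
    Omega = offdiag_const * S
    np.fill_diagonal(Omega, diag_const)
    try:
        linalg.cholesky(Omega, lower=True)
    except linalg.LinAlgError as exc:
        lam_min = float(np.linalg.eigvalsh(Omega)[0])
        raise ValueError(
            f"constructed covariance is not positive definite "
            f"(smallest eigenvalue {lam_min:.3e}); increase diag_const"
        ) from exc
    return Omega


def sample_data(Omega, n_samples: int, seed: int = 0) -> np.ndarray:
    """N i.i.d. draws from MVN(0, Omega), reproducible given the seed."""
    Omega = np.asarray(Omega, dtype=float)
    try:
        L = linalg.cholesky(Omega, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError("Omega must be positive definite") from exc
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_samples, Omega.shape[0]))
    return Z @ L.T


@dataclass(frozen=True)
class NetworkSpec:
    """One ground-truth configuration of the recovery study."""

    name: str
    p_extra: float
    offdiag_const: float


DEFAULT_NETWORKS = (
    NetworkSpec("S1", S1_P_EXTRA, S1_OFFDIAG),
    NetworkSpec("S2", S2_P_EXTRA, S2_OFFDIAG),
)


@dataclass
class StudyConfig:
    """Design of a full recovery experiment.

    One fresh solution network and data set is drawn per (network, N,
    replicate) cell from a seed derived from the master seed and the cell
    coordinates, so every cell is independently reproducible.
    """

    K: int = 68
    sample_sizes: tuple = (100, 250, 500, 1000)
    replicates: int = 10
    networks: tuple = DEFAULT_NETWORKS
    mnl: Mapping | None = field(default_factory=dict)
    ppc_grid: tuple = ()
    glasso_grid: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(n < 2 for n in self.sample_sizes):
            raise ValueError("all sample sizes must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "networks" in raw:
            raw["networks"] = tuple(NetworkSpec(**n) for n in raw["networks"])
        for key in ("sample_sizes", "ppc_grid", "glasso_grid"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _score_row(base: dict, adjacency, truth, **extra) -> dict:
    s = score_network(adjacency, truth)
    return {
        **base,
        **extra,
        "tp": s.tp,
        "fp": s.fp,
        "tn": s.tn,
        "fn": s.fn,
        "sensitivity": s.sensitivity,
        "specificity": s.specificity,
        "error": "",
    }


def run_simulation_study(study: StudyConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full recovery experiment and return a tidy results table.

    For every (network, N, replicate): draw a fresh truth network, build its
    covariance, sample the data, run each enabled estimator (MNL if
    ``study.mnl`` is not None; PPC and gLASSO over their grids), and score
    against the truth. One row per estimator evaluation; a failed evaluation
    is recorded with its error message, never silently dropped.
    """
    rows: list[dict] = []
    for net_index, net in enumerate(study.networks):
        for n_samples in study.sample_sizes:
            for rep in range(study.replicates):
                cell_seed = [study.seed, net_index, int(n_samples), rep]
                truth = generate_solution_network(
                    study.K, net.p_extra, seed=cell_seed + [0]
                )
                Omega = network_to_covariance(truth, net.offdiag_const)
                B = sample_data(Omega, n_samples, seed=cell_seed + [1])
                # MNL and PPC see standardized columns, matching the real-data
                # preprocessing; gLASSO sees the raw draws so its penalty acts
                # on the covariance scale the lambda grid was designed for.
                B_std = (B - B.mean(axis=0)) / B.std(axis=0, ddof=1)
                base = {"network": net.name, "N": n_samples, "replicate": rep}
                if progress:  # pragma: no cover
                    print(f"[netsim] {net.name} N={n_samples} rep={rep}", flush=True)

                def record(method, tuning, builder):
                    try:
                        rows.append(
                            _score_row(
                                base, builder(), truth, method=method, tuning=tuning
                            )
                        )
                    except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                        rows.append(
                            {
                                **base,
                                "method": method,
                                "tuning": tuning,
                                "tp": np.nan,
                                "fp": np.nan,
                                "tn": np.nan,
                                "fn": np.nan,
                                "sensitivity": np.nan,
                                "specificity": np.nan,
                                "error": f"{type(exc).__name__}: {exc}",
                            }
                        )

                if study.mnl is not None:
                    params = dict(study.mnl)
                    params.setdefault(
                        "random_state",
                        int(
                            np.random.SeedSequence(cell_seed + [2]).generate_state(1)[0]
                            % (2**31)
                        ),
                    )
                    record(
                        "mnl",
                        np.nan,
                        lambda p=params, D=B_std: MNLNetwork(**p).fit(D).adjacency_,
                    )
                for tau in study.ppc_grid:
                    record("ppc", tau, lambda t=tau, D=B_std: ppc_network(D, t))
                for lam in study.glasso_grid:
                    record("glasso", lam, lambda l=lam, D=B: glasso_network(D, l))
    cols = [
        "network", "N", "replicate", "method", "tuning",
        "tp", "fp", "tn", "fn", "sensitivity", "specificity", "error",
    ]
    return pd.DataFrame(rows, columns=cols)


def simulate_cohort(
    n_subjects: int = 200,
    K: int = 68,
    network: np.ndarray | None = None,
    gamma: float = 0.9,
    sigma2: float = 1.0,
    seed: int = 0,
):
    """Synthetic ROI-by-subject cohort with covariate effects and CAR noise.

    Emulates a cortical-thickness study table: each subject gets an age
    (normal, mean 73, sd 6 years), sex and risk-allele carrier status
    (Bernoulli), and per-ROI measurements equal to a baseline plus linear
    covariate effects plus spatially correlated noise drawn from the CAR
    model on a known network. Residualising the returned ROI table on the
    covariate table should recover the network's covariance signature.

    Returns
    -------
    roi : DataFrame of shape (n_subjects, K + 1)
        ``participant_id`` plus one column per ROI, units mm.
    covariates : DataFrame
        ``participant_id``, ``age``, ``sex``, ``carrier``.
    network : ndarray
        The ground-truth adjacency matrix of the noise field.
    """
    from .car import build_precision

    rng = np.random.default_rng(seed)
    if network is None:
        network = generate_solution_network(K, p_extra=0.05, seed=seed)
    network = check_adjacency(network)
    K = network.shape[0]
    age = rng.normal(73.0, 6.0, n_subjects)
    sex = rng.integers(0, 2, n_subjects).astype(float)
    carrier = rng.integers(0, 2, n_subjects).astype(float)

    Q_inv = build_precision(network, gamma)
    cov = sigma2 * np.linalg.inv(Q_inv)
    noise = rng.multivariate_normal(np.zeros(K), cov, size=n_subjects, method="cholesky")

    beta_age, beta_sex, beta_carrier = -0.01, 0.05, -0.08  # mm per unit
    mean = 2.7 + beta_age * (age - 73.0)[:, None] + beta_sex * sex[:, None]
    mean = mean + beta_carrier * carrier[:, None]
    values = mean + 0.1 * noise

    ids = [f"sub-{i:04d}" for i in range(n_subjects)]
    roi = pd.DataFrame(values, columns=[f"roi_{k + 1:02d}" for k in range(K)])
    roi.insert(0, "participant_id", ids)
    covariates = pd.DataFrame(
        {"participant_id": ids, "age": age, "sex": sex, "carrier": carrier}
    )
    return roi, covariates, network
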