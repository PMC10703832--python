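"""Synthetic FOT cohort generator.

Emulates the distributional structure of published MostGraph cohorts: sex-
and group-stratified marginal means and SDs for the 10 phase measurements,
configurable right-skew via a generative Yeo-Johnson shape, and a Gaussian
copula for inter-item correlation.  Defaults reproduce the printed group
summaries of a healthy-adult reference cohort (215 controls: 101 male, 114
female) and an untreated asthma/cough-variant-asthma cohort (941 patients:
294 male, 647 female).

Generative model per stratum: draw latent Z ~ N(0, C), then per dimension j

    y_j = psi_inv(m_j + s_j * Z_j ; lambda_j)

where (m_j, s_j) are calibrated by moment matching so the measurement-scale
mean and SD hit their targets.  lambda = 1 gives Gaussian margins; lambda < 1
gives right skew for positive quantities.  Draws violating positivity of
resistances or resonant frequency are rejected and redrawn per subject.
The marginal moments are published facts; the correlation defaults encode
qualitative respiratory mechanics only and are not instrument claims.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import optimize

from .fot_data import (
    Cohort,
    FotItem,
    FotRecord,
    PHASE_COLUMNS,
    PHASE_ITEMS,
    complete_derived,
)
from .yeo_johnson import yj_attainable_bounds, yj_forward, yj_inverse

__all__ = [
    "MarginalSpec",
    "CohortSpec",
    "GenerationParams",
    "default_spec",
    "default_correlation",
    "repair_correlation",
    "calibrate",
    "generate_cohort",
    "generate_study_cohort",
    "load_spec",
    "save_spec",
    "STUDY_N",
]

# columns whose draws must be strictly positive (resistances, resonant freq)
_POSITIVE_COLUMNS = tuple(
    c for c in PHASE_COLUMNS if c.split("_")[0] in {"R5", "R20", "Fres"}
)
_MIN_AGE = 16.0

#: published stratum sizes (controls / patients, by sex)
STUDY_N = {
    ("male", "control"): 101,
    ("female", "control"): 114,
    ("male", "asthma"): 294,
    ("female", "asthma"): 647,
}

# mean, sd of each phase measurement per (sex, group), in PHASE_COLUMNS
# order-independent dict form; from the published cohort summary tables
_TABLE_MARGINALS: dict[tuple[str, str], dict[str, tuple[float, float]]] = {
    ("male", "control"): {
        "R5_in": (2.05, 0.92), "R5_ex": (2.50, 1.22),
        "R20_in": (2.04, 0.77), "R20_ex": (2.30, 0.91),
        "X5_in": (-0.24, 0.30), "X5_ex": (-0.12, 0.40),
        "Fres_in": (6.53, 1.73), "Fres_ex": (5.97, 2.24),
        "ALX_in": (0.98, 1.02), "ALX_ex": (0.79, 2.19),
    },
    ("female", "control"): {
        "R5_in": (2.36, 0.69), "R5_ex": (3.01, 1.01),
        "R20_in": (2.42, 0.66), "R20_ex": (2.81, 0.83),
        "X5_in": (-0.43, 0.34), "X5_ex": (-0.24, 0.45),
        "Fres_in": (7.34, 1.72), "Fres_ex": (6.41, 2.15),
        "ALX_in": (1.63, 1.39), "ALX_ex": (1.15, 2.12),
    },
    ("male", "asthma"): {
        "R5_in": (2.72, 1.11), "R5_ex": (3.19, 1.29),
        "R20_in": (2.34, 0.81), "R20_ex": (2.72, 0.97),
        "X5_in": (-0.47, 0.56), "X5_ex": (-0.45, 0.87),
        "Fres_in": (8.04, 3.09), "Fres_ex": (7.95, 4.22),
        "ALX_in": (2.23, 4.82), "ALX_ex": (2.78, 8.00),
    },
    ("female", "asthma"): {
        "R5_in": (3.19, 1.37), "R5_ex": (3.86, 1.75),
        "R20_in": (2.77, 1.01), "R20_ex": (3.30, 1.22),
        "X5_in": (-0.57, 0.69), "X5_ex": (-0.64, 1.34),
        "Fres_in": (8.30, 3.11), "Fres_ex": (8.52, 4.83),
        "ALX_in": (2.76, 5.20), "ALX_ex": (4.09, 10.99),
    },
}

_TABLE_AGES = {
    ("male", "control"): (39.3, 14.8),
    ("female", "control"): (29.7, 10.8),
    ("male", "asthma"): (42.1, 16.0),
    ("female", "asthma"): (42.5, 15.9),
}

#: default generative shape: right-skewed resistances / Fres / ALX,
#: symmetric reactance
_DEFAULT_SKEW = {"R5": 0.5, "R20": 0.5, "Fres": 0.5, "ALX": 0.5, "X5": 1.0}


@dataclass(frozen=True)
class MarginalSpec:
    """Target measurement-scale mean/SD and generative shape for one dimension."""

    target_mean: float
    target_sd: float
    skew_lambda: float = 1.0

    def __post_init__(self) -> None:
        if not (self.target_sd > 0):
            raise ValueError("target_sd must be positive")
        if not np.isfinite(self.skew_lambda):
            raise ValueError("skew_lambda must be finite")


def default_correlation() -> np.ndarray:
    """Default 10x10 latent correlation over PHASE_COLUMNS.

    Separable (Kronecker) structure: a 5x5 cross-quantity block A — R5-R20
    +0.5, R5-Fres +0.5, R5-X5 -0.5, X5-ALX -0.5, Fres-ALX +0.5, zero
    otherwise — times a 2x2 within-breath block with inhale/exhale
    correlation 0.8, so C[(q,p),(q',p')] = A[q,q'] * P[p,p'].  The
    separability keeps the matrix near-PSD: cross-phase cross-quantity
    entries inherit 0.8x the same-phase value rather than dropping to zero,
    which would make the matrix strongly indefinite and let the PSD repair
    wash out the configured inhale/exhale coupling.
    """
    quantities = ("R5", "R20", "X5", "Fres", "ALX")
    A = np.eye(len(quantities))

    def _set(a: str, b: str, rho: float) -> None:
        i, j = quantities.index(a), quantities.index(b)
        A[i, j] = A[j, i] = rho

    _set("R5", "R20", 0.5)
    _set("R5", "Fres", 0.5)
    _set("R5", "X5", -0.5)
    _set("X5", "ALX", -0.5)
    _set("Fres", "ALX", 0.5)
    P = np.array([[1.0, 0.8], [0.8, 1.0]])
    # PHASE_COLUMNS is quantity-major with (in, ex) inside each quantity
    return np.kron(A, P)


def repair_correlation(C: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Nearest-ish PSD repair: clip eigenvalues, renormalise to unit diagonal."""
    C = np.asarray(C, dtype=float)
    if C.shape != (len(PHASE_COLUMNS), len(PHASE_COLUMNS)) and C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(C, C.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    if np.any(np.abs(C) > 1 + 1e-12):
        raise ValueError("correlation entries must lie in [-1, 1]")
    w, V = np.linalg.eigh(C)
    if w.min() >= eig_floor:
        return C
    w = np.clip(w, eig_floor, None)
    R = (V * w) @ V.T
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class CohortSpec:
    """Generative spec for one (sex, group) stratum."""

    sex: str
    group: str
    marginals: dict[str, MarginalSpec]  # keyed by phase column name
    correlation: np.ndarray = field(default_factory=default_correlation)
    age_mean: float = 40.0
    age_sd: float = 15.0
    n: int = 0

    def __post_init__(self) -> None:
        missing = set(PHASE_COLUMNS) - set(self.marginals)
        if missing:
            raise ValueError(f"marginals missing for {sorted(missing)}")
        if self.n < 0:
            raise ValueError("n must be >= 0")
        self.correlation = np.asarray(self.correlation, dtype=float)


@dataclass
class GenerationParams:
    """Calibrated transformed-space location/scale per phase column."""

    m: dict[str, float]
    s: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.s.values()):
            raise ValueError("calibrated scale must be positive")


def default_spec(sex: str, group: str, n: int | None = None) -> CohortSpec:
    """Stratum spec with the published marginal moments and cohort size."""
    key = (sex, group)
    if key not in _TABLE_MARGINALS:
        raise ValueError(f"no default spec for sex={sex!r}, group={group!r}")
    marginals = {
        col: MarginalSpec(m, sd, _DEFAULT_SKEW[col.split("_")[0]])
        for col, (m, sd) in _TABLE_MARGINALS[key].items()
    }
    age_mean, age_sd = _TABLE_AGES[key]
    return CohortSpec(
        sex=sex,
        group=group,
        marginals=marginals,
        correlation=default_correlation(),
        age_mean=age_mean,
        age_sd=age_sd,
        n=STUDY_N[key] if n is None else int(n),
    )


def _inv_clipped(x: np.ndarray, lam: float) -> np.ndarray:
    """psi_inv with arguments nudged inside the attainable open interval."""
    lo, hi = yj_attainable_bounds(lam)
    eps = 1e-12
    if np.isfinite(lo):
        x = np.maximum(x, lo + max(abs(lo), 1.0) * eps)
    if np.isfinite(hi):
        x = np.minimum(x, hi - max(abs(hi), 1.0) * eps)
    return yj_inverse(x, lam)


def _calibrate_dim(spec: MarginalSpec, z: np.ndarray) -> tuple[float, float]:
    lam = spec.skew_lambda
    if lam == 1.0:
        # identity transform: moments match exactly
        return spec.target_mean, spec.target_sd

    # first-order initial guess via the delta method at the target mean
    m0 = float(yj_forward(spec.target_mean, lam))
    y0 = spec.target_mean
    dpsi = (y0 + 1.0) ** (lam - 1.0) if y0 >= 0 else (1.0 - y0) ** (1.0 - lam)
    s0 = spec.target_sd * dpsi

    def resid(p: np.ndarray) -> np.ndarray:
        m, log_s = p
        y = _inv_clipped(m + np.exp(log_s) * z, lam)
        return np.array(
            [
                (y.mean() - spec.target_mean) / spec.target_sd,
                np.log(max(y.std(), 1e-300) / spec.target_sd),
            ]
        )

    sol = optimize.least_squares(
        resid, x0=[m0, np.log(max(s0, 1e-6))], xtol=1e-12, ftol=1e-12, max_nfev=200
    )
    err = resid(sol.x)
    if abs(err[0]) > 0.02 or abs(err[1]) > np.log(1.02):
        raise RuntimeError(
            f"moment calibration failed for lambda={lam}, "
            f"targets ({spec.target_mean}, {spec.target_sd})"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def calibrate(spec: CohortSpec, n_mc: int = 200_000, seed: int = 0) -> GenerationParams:
    """Match transformed-space (m, s) to the measurement-scale targets.

    Uses least-squares moment matching on a fixed standard-normal sample of
    size ``n_mc`` (common random numbers), so the Monte-Carlo mean is within
    2% of target_sd and the SD within 2% relative, per dimension.
    """
    if n_mc < 10**5:
        raise ValueError("n_mc must be at least 1e5 for stable moment matching")
    z = np.random.default_rng(seed).standard_normal(n_mc)
    m: dict[str, float] = {}
    s: dict[str, float] = {}
    for col in PHASE_COLUMNS:
        try:
            m[col], s[col] = _calibrate_dim(spec.marginals[col], z)
        except RuntimeError as exc:
            raise RuntimeError(f"dimension {col}: {exc}") from exc
    return GenerationParams(m=m, s=s)


def generate_cohort(
    spec: CohortSpec,
    seed: int = 0,
    params: GenerationParams | None = None,
    id_prefix: str | None = None,
) -> Cohort:
    """Draw ``spec.n`` records from the calibrated Gaussian-copula model.

    Per-subject rejection sampling enforces strict positivity of R5, R20 and
    Fres phases (no probability atoms at 0); ages are normal truncated at 16.
    Identical (spec, seed) always yields the identical cohort.
    """
    rng = np.random.default_rng(seed)
    if params is None:
        params = calibrate(spec, seed=0)
    n = spec.n
    prefix = id_prefix if id_prefix is not None else f"{spec.group[:4]}_{spec.sex[0]}"
    if n == 0:
        return Cohort(records=[], provenance=f"synthetic:{spec.sex}/{spec.group}")

    C = repair_correlation(spec.correlation)
    L = np.linalg.cholesky(C)
    lam = np.array([spec.marginals[c].skew_lambda for c in PHASE_COLUMNS])
    m = np.array([params.m[c] for c in PHASE_COLUMNS])
    s = np.array([params.s[c] for c in PHASE_COLUMNS])
    pos_idx = [PHASE_COLUMNS.index(c) for c in _POSITIVE_COLUMNS]

    rows = np.empty((n, len(PHASE_COLUMNS)))
    filled = 0
    attempted = 0
    while filled < n:
        want = n - filled
        Z = rng.standard_normal((want, len(PHASE_COLUMNS))) @ L.T
        X = m + s * Z
        Y = np.column_stack(
            [_inv_clipped(X[:, j], lam[j]) for j in range(len(PHASE_COLUMNS))]
        )
        ok = np.all(Y[:, pos_idx] > 0, axis=1)
        attempted += want
        k = int(ok.sum())
        rows[filled : filled + k] = Y[ok]
        filled += k
        if attempted >= 2 * n and filled < attempted / 2:
            raise RuntimeError(
                "rejection rate above 50%: revise the cohort spec "
                "(targets imply mass at non-physical values)"
            )

    ages = np.empty(n)
    a_filled = 0
    while a_filled < n:
        draw = rng.normal(spec.age_mean, spec.age_sd, size=n - a_filled)
        draw = draw[draw >= _MIN_AGE]
        ages[a_filled : a_filled + draw.size] = draw
        a_filled += draw.size

    width = len(str(n))
    records = []
    for i in range(n):
        vals = {
            PHASE_ITEMS[j]: float(rows[i, j]) for j in range(len(PHASE_COLUMNS))
        }
        rec = FotRecord(
            subject_id=f"{prefix}_{i + 1:0{width}d}",
            sex=spec.sex,
            group=spec.group,
            age=float(ages[i]),
            values=vals,
        )
        records.append(complete_derived(rec))
    return Cohort(records=records, provenance=f"synthetic:{spec.sex}/{spec.group}")


def save_spec(spec: CohortSpec, path) -> None:
    """Serialize a stratum spec as YAML (or JSON if the path ends in .json)."""
    import json

    import yaml

    payload = {
        "sex": spec.sex,
        "group": spec.group,
        "n": spec.n,
        "age_mean": spec.age_mean,
        "age_sd": spec.age_sd,
        "marginals": {
            col: {
                "mean": m.target_mean,
                "sd": m.target_sd,
                "skew_lambda": m.skew_lambda,
            }
            for col, m in spec.marginals.items()
        },
        "correlation": np.asarray(spec.correlation).tolist(),
    }
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


def load_spec(path) -> CohortSpec:
    """Read a stratum spec from a YAML or JSON file written by save_spec."""
    import json

    import yaml

    path = str(path)
    with open(path) as fh:
        payload = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    marginals = {
        col: MarginalSpec(d["mean"], d["sd"], d.get("skew_lambda", 1.0))
        for col, d in payload["marginals"].items()
    }
    corr = payload.get("correlation")
    return CohortSpec(
        sex=payload["sex"],
        group=payload["group"],
        marginals=marginals,
        correlation=default_correlation() if corr is None else np.asarray(corr, float),
        age_mean=float(payload.get("age_mean", 40.0)),
        age_sd=float(payload.get("age_sd", 15.0)),
        n=int(payload.get("n", 0)),
    )


def generate_study_cohort(
    seed: int = 0,
    n_by_stratum: Mapping[tuple[str, str], int] | None = None,
) -> Cohort:
    """Full four-stratum synthetic study cohort (default: published sizes).

    Independent seed streams per stratum so one stratum can be regenerated
    without disturbing the others.
    """
    sizes = dict(STUDY_N)
    if n_by_stratum:
        sizes.update(n_by_stratum)
    children = np.random.SeedSequence(seed).spawn(len(STUDY_N))
    records = []
    for child, (key, _) in zip(children, sorted(STUDY_N.items())):
        spec = default_spec(*key, n=sizes[key])
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        sub = generate_cohort(spec, seed=sub_seed)
        records.extend(sub.records)
    return Cohort(records=records, provenance=f"synthetic:study(seed={seed})")
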