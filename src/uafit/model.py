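"""Correlation-structure confirmatory factor models.

A model is a pattern of free loadings K (p variables on q factors) plus a set
of free factor correlations Phi (unit diagonal, factor variances fixed to 1
for identification).  The model-implied correlation matrix is K Phi K' with
the diagonal replaced by 1: residual variances absorb whatever is left, so
only the p(p-1)/2 off-diagonal elements carry information.

The module also builds the population models of the simulation design: a
q*-factor simple structure with an additional independent "misfit" factor
whose loadings generate a controlled approximation error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vech import n_pairs, pair_indices, vech_off


@dataclass(frozen=True)
class ModelSpec:
    """A loading pattern and the set of free factor correlations.

    Parameters are ordered canonically: free loadings column-major over the
    pattern (factor by factor), then free factor correlations over the strict
    lower triangle of Phi, column-major.
    """

    loading_pattern: np.ndarray  # bool, p x q
    phi_free: np.ndarray | None = None  # bool, q x q symmetric, diagonal ignored
    var_names: tuple[str, ...] | None = None
    factor_names: tuple[str, ...] | None = None

    def __post_init__(self):
        pat = np.asarray(self.loading_pattern, dtype=bool)
        object.__setattr__(self, "loading_pattern", pat)
        if pat.ndim != 2:
            raise ValueError("loading_pattern must be a p x q boolean matrix")
        p, q = pat.shape
        if self.phi_free is None:
            phi = np.ones((q, q), dtype=bool)
        else:
            phi = np.asarray(self.phi_free, dtype=bool)
            if phi.shape != (q, q):
                raise ValueError("phi_free must be q x q")
            if not np.array_equal(phi, phi.T):
                raise ValueError("phi_free must be symmetric")
        np.fill_diagonal(phi, False)
        object.__setattr__(self, "phi_free", phi)
        if not pat.any(axis=1).all():
            bad = [i for i in range(p) if not pat[i].any()]
            raise ValueError(f"variables {bad} load on no factor")
        # df may be negative for toy structures evaluated pointwise; fitting
        # such a model is rejected in fit()

    @property
    def p(self) -> int:
        return self.loading_pattern.shape[0]

    @property
    def q(self) -> int:
        return self.loading_pattern.shape[1]

    @property
    def n_loadings(self) -> int:
        return int(self.loading_pattern.sum())

    @property
    def n_phi(self) -> int:
        return int(np.tril(self.phi_free, -1).sum())

    @property
    def n_params(self) -> int:
        return self.n_loadings + self.n_phi

    @property
    def df(self) -> int:
        return n_pairs(self.p) - self.n_params

    # -- parameter packing ------------------------------------------------
    def unpack(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """theta -> (K, Phi)."""
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_params,):
            raise ValueError(
                f"theta has length {theta.size}, expected {self.n_params}"
            )
        K = np.zeros((self.p, self.q))
        K.T[self.loading_pattern.T] = theta[: self.n_loadings]
        Phi = np.eye(self.q)
        c = self.n_loadings
        for j in range(self.q):
            for i in range(j + 1, self.q):
                if self.phi_free[i, j]:
                    Phi[i, j] = Phi[j, i] = theta[c]
                    c += 1
        return K, Phi

    def pack(self, K: np.ndarray, Phi: np.ndarray) -> np.ndarray:
        theta = np.empty(self.n_params)
        theta[: self.n_loadings] = np.asarray(K, dtype=float).T[self.loading_pattern.T]
        c = self.n_loadings
        for j in range(self.q):
            for i in range(j + 1, self.q):
                if self.phi_free[i, j]:
                    theta[c] = Phi[i, j]
                    c += 1
        return theta

    def default_start(self) -> np.ndarray:
        return np.concatenate(
            [np.full(self.n_loadings, 0.5), np.full(self.n_phi, 0.3)]
        )


def simple_structure(p: int, q: int) -> ModelSpec:
    """Simple-structure CFA: p/q variables per factor, all factor corrs free."""
    if p % q:
        raise ValueError(f"p={p} not divisible by q={q}")
    m = p // q
    pat = np.zeros((p, q), dtype=bool)
    for b in range(q):
        pat[b * m : (b + 1) * m, b] = True
    return ModelSpec(pat)


def implied_matrix(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Model-implied correlation matrix K Phi K' with unit diagonal."""
    K, Phi = spec.unpack(theta)
    S = K @ Phi @ K.T
    np.fill_diagonal(S, 1.0)
    return S


def implied_correlations(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    """Off-diagonal model-implied correlations in canonical ordering."""
    sig = vech_off(implied_matrix(theta, spec))
    if np.any(np.abs(sig) >= 1.0):
        raise ValueError("inadmissible theta: an implied correlation is >= 1 in magnitude")
    return sig


def jacobian(theta: np.ndarray, spec: ModelSpec, method: str = "analytic") -> np.ndarray:
    """Derivatives of the implied correlations w.r.t. the free parameters.

    Delta[a, t] = d sigma_a / d theta_t, with rows in the canonical pair
    ordering and columns in the canonical parameter ordering.  The analytic
    form follows from Sigma = K Phi K' (the fixed unit diagonal does not enter
    the off-diagonal derivatives); a central finite-difference version is kept
    as an independent check.
    """
    if method == "fd":
        return _jacobian_fd(theta, spec)
    theta = np.asarray(theta, dtype=float)
    K, Phi = spec.unpack(theta)
    p, q = spec.p, spec.q
    rows, cols = pair_indices(p)
    m = rows.size
    Delta = np.empty((m, spec.n_params))
    KP = K @ Phi  # p x q
    t = 0
    # loadings, column-major over the pattern
    for f in range(q):
        for v in range(p):
            if not spec.loading_pattern[v, f]:
                continue
            # dSigma = e_v (K Phi)_{., f}' + (K Phi)_{., f} e_v'
            col = np.zeros(m)
            mask_i = rows == v
            col[mask_i] = KP[cols[mask_i], f]
            mask_j = cols == v
            col[mask_j] += KP[rows[mask_j], f]
            Delta[:, t] = col
            t += 1
    # factor correlations, lower triangle column-major
    for j in range(q):
        for i in range(j + 1, q):
            if not spec.phi_free[i, j]:
                continue
            Delta[:, t] = K[rows, i] * K[cols, j] + K[rows, j] * K[cols, i]
            t += 1
    return Delta


def _jacobian_fd(theta: np.ndarray, spec: ModelSpec) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    m = n_pairs(spec.p)
    Delta = np.empty((m, spec.n_params))
    for t in range(spec.n_params):
        h = 1e-6 * max(1.0, abs(theta[t]))
        up = theta.copy()
        dn = theta.copy()
        up[t] += h
        dn[t] -= h
        Delta[:, t] = (
            vech_off(implied_matrix(up, spec)) - vech_off(implied_matrix(dn, spec))
        ) / (2 * h)
    return Delta


# ---------------------------------------------------------------------------
# population models of the simulation design
# ---------------------------------------------------------------------------

#: Misfit type I: the extra factor loads +k* on the first half of each
#: factor's indicator block and -k* on the second half (balanced pattern).
#: Misfit type II: the extra factor loads +k* on the first and last indicator
#: of each block only (sparse pattern).
MISFIT_TYPES = ("I", "II")


@dataclass(frozen=True)
class PopulationModel:
    """A q*+1-factor population generating a known approximation error."""

    K: np.ndarray
    Phi: np.ndarray
    Psi: np.ndarray
    Sigma0: np.ndarray
    misfit_type: str
    k: float
    k_star: float
    q_star: int

    @property
    def p(self) -> int:
        return self.Sigma0.shape[0]

    @property
    def sigma0(self) -> np.ndarray:
        """Population correlations in canonical ordering."""
        return vech_off(self.Sigma0)

    def analysis_spec(self) -> ModelSpec:
        """The q*-factor analysis model (misfit factor excluded)."""
        return simple_structure(self.p, self.q_star)


def build_population_model(
    q_star: int,
    p: int,
    misfit_type: str,
    k: float,
    k_star: float,
    phi_offdiag: float = 0.3,
) -> PopulationModel:
    """Assemble Sigma0 = K Phi K' + Psi for a simulation condition.

    The first q* factors carry a simple structure with common loading ``k``
    on equal blocks of p/q* indicators and pairwise correlation
    ``phi_offdiag``; the (q*+1)-th factor is independent of them and carries
    the misfit loadings ``k_star`` in the pattern selected by
    ``misfit_type``.  Psi completes the unit diagonal.
    """
    if misfit_type not in MISFIT_TYPES:
        raise ValueError(f"misfit_type must be one of {MISFIT_TYPES}")
    if p % q_star:
        raise ValueError(f"p={p} not divisible by q*={q_star}")
    q = q_star + 1
    m = p // q_star
    K = np.zeros((p, q))
    for b in range(q_star):
        K[b * m : (b + 1) * m, b] = k
    if misfit_type == "I":
        half = m // 2
        for b in range(q_star):
            K[b * m : b * m + half, q_star] = k_star
            K[b * m + half : (b + 1) * m, q_star] = -k_star
    else:
        for b in range(q_star):
            K[b * m, q_star] = k_star
            K[(b + 1) * m - 1, q_star] = k_star
    Phi = np.eye(q)
    Phi[:q_star, :q_star] = phi_offdiag
    np.fill_diagonal(Phi, 1.0)
    communality = np.einsum("ij,jk,ik->i", K, Phi, K)
    if np.any(communality >= 1.0):
        raise ValueError(
            f"communalities reach {communality.max():.3f} >= 1; "
            "loadings k, k* are too large"
        )
    Psi = np.diag(1.0 - communality)
    Sigma0 = K @ Phi @ K.T + Psi
    if np.linalg.eigvalsh(Sigma0)[0] <= 0:
        raise ValueError("Sigma0 is not positive definite")
    return PopulationModel(
        K=K, Phi=Phi, Psi=Psi, Sigma0=Sigma0,
        misfit_type=misfit_type, k=float(k), k_star=float(k_star), q_star=q_star,
    )


# ---------------------------------------------------------------------------
# structured-text model specification
# ---------------------------------------------------------------------------

def parse_model_spec(text: str) -> ModelSpec:
    """Parse a plain-text model specification.

    Format, one directive per line (``#`` comments allowed)::

        variables: x1 x2 x3 x4 x5 x6 x7 x8
        factor f1: x1 x2 x3 x4
        factor f2: x5 x6 x7 x8
        uncorrelated: f1 f2        # optional; factor pairs are free by default

    The ``variables:`` line is optional; without it the variable order is the
    order of first appearance in the factor lines.
    """
    var_names: list[str] = []
    factors: list[tuple[str, list[str]]] = []
    uncorrelated: list[tuple[str, str]] = []
    explicit_vars = False
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"line {ln}: expected 'directive: ...', got {raw!r}")
        head, _, rest = line.partition(":")
        head = head.strip().lower()
        tokens = rest.split()
        if head == "variables":
            if explicit_vars:
                raise ValueError(f"line {ln}: duplicate 'variables:' directive")
            if not tokens:
                raise ValueError(f"line {ln}: 'variables:' lists no names")
            if len(set(tokens)) != len(tokens):
                raise ValueError(f"line {ln}: duplicate variable names")
            var_names = tokens
            explicit_vars = True
        elif head.startswith("factor"):
            name = head[len("factor"):].strip() or f"f{len(factors) + 1}"
            if name in [f for f, _ in factors]:
                raise ValueError(f"line {ln}: duplicate factor {name!r}")
            if not tokens:
                raise ValueError(f"line {ln}: factor {name!r} lists no indicators")
            for v in tokens:
                if explicit_vars and v not in var_names:
                    raise ValueError(f"line {ln}: unknown variable {v!r}")
                if not explicit_vars and v not in var_names:
                    var_names.append(v)
            factors.append((name, tokens))
        elif head == "uncorrelated":
            if len(tokens) != 2:
                raise ValueError(f"line {ln}: 'uncorrelated:' needs two factor names")
            uncorrelated.append((tokens[0], tokens[1]))
        else:
            raise ValueError(f"line {ln}: unknown directive {head!r}")
    if not factors:
        raise ValueError("model specification contains no 'factor' lines")
    fnames = [f for f, _ in factors]
    pat = np.zeros((len(var_names), len(factors)), dtype=bool)
    for fj, (_, vs) in enumerate(factors):
        for v in vs:
            pat[var_names.index(v), fj] = True
    phi = np.ones((len(factors), len(factors)), dtype=bool)
    for a, b in uncorrelated:
        for nm in (a, b):
            if nm not in fnames:
                raise ValueError(f"'uncorrelated:' names unknown factor {nm!r}")
        ia, ib = fnames.index(a), fnames.index(b)
        phi[ia, ib] = phi[ib, ia] = False
    return ModelSpec(
        pat, phi_free=phi, var_names=tuple(var_names), factor_names=tuple(fnames)
    )
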