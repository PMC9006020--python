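"""Reversible amino-acid substitution models with discrete-gamma rate heterogeneity.

A model couples a symmetric exchangeability matrix ``s`` with stationary
frequencies ``pi`` into the rate matrix ``Q_ij = s_ij * pi_j`` (i != j),
normalized to one expected substitution per site per unit branch length
(``-sum_i pi_i Q_ii = 1``).  Among-site rate variation follows the discrete
gamma approximation: ``k`` equiprobable categories, each category rate being
the mean of its gamma quantile bin, so the category rates average to 1.

The empirical LG and WAG tables ship as plain-text data files (PAML row
order) whose checksums are verified at load time; the Poisson model
(uniform exchangeabilities and frequencies) is available for closed-form
checks.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
N_STATES = 20

#: Characters treated as fully missing (marginalized in the likelihood).
#: Ambiguity codes are not expanded into partial state sets.
MISSING_CHARS = frozenset("-?XBZJUO*")

_TABLE_CHECKSUMS = {
    "lg": "51ba0250c5c272bc8e569bb5f98d97cc74d81d77972795b8f674ca905b50a337",
    "wag": "0fd482baf0b59da651f450ef038de6ee27354bdab136b863cebc76ecc10f258b",
}

#: Pseudo-frequency floor applied to unobserved states in "+F" mode.
FREQ_FLOOR = 1e-4


class ModelError(ValueError):
    """Invalid substitution-model parameter or specification."""


def _load_table(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Load an embedded exchangeability table; returns (s 20x20, freqs)."""
    ref = resources.files("phylodissect.data") / f"{name}.dat"
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _TABLE_CHECKSUMS[name]:
        raise ModelError(f"checksum mismatch for embedded model table {name!r}")
    rows = [
        [float(x) for x in line.split()]
        for line in raw.decode().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    s = np.zeros((N_STATES, N_STATES))
    for i, row in enumerate(rows[:-1], start=1):
        s[i, : len(row)] = row
    s = s + s.T
    freqs = np.asarray(rows[-1])
    freqs = freqs / freqs.sum()
    return s, freqs


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-of-bin rates for the k-category discrete gamma (mean 1).

    Bin edges are the j/k quantiles of Gamma(alpha, rate=alpha); each
    category rate is the conditional mean of its bin, so the rates
    average exactly to 1.
    """
    if k < 1:
        raise ModelError(f"category count must be >= 1, got {k}")
    if alpha <= 0:
        raise ModelError(f"gamma shape must be positive, got {alpha}")
    if k == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(1, k) / k, alpha, scale=1.0 / alpha)
    # integral of x f(x) over a bin of Gamma(shape a, rate a) is the
    # regularized incomplete gamma with shape a+1 at rate-scaled edges
    upper = np.concatenate([gammainc(alpha + 1, edges * alpha), [1.0]])
    lower = np.concatenate([[0.0], gammainc(alpha + 1, edges * alpha)])
    rates = k * (upper - lower)
    return rates / rates.mean()  # guard tiny numerical drift


@dataclass(frozen=True)
class SubstitutionModel:
    """Reversible 20-state model with discrete-gamma rate heterogeneity.

    Attributes
    ----------
    name : model family ("LG", "WAG" or "Poisson")
    exchangeabilities : symmetric 20x20 matrix (diagonal ignored)
    frequencies : stationary frequencies, summing to 1
    alpha : gamma shape; irrelevant when k == 1
    k : number of equiprobable rate categories
    """

    name: str
    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    alpha: float = 1.0
    k: int = 4
    _eig: tuple = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.k < 1:
            raise ModelError(f"category count must be >= 1, got {self.k}")
        if self.alpha <= 0:
            raise ModelError(f"gamma shape must be positive, got {self.alpha}")
        pi = np.asarray(self.frequencies, dtype=float)
        if pi.shape != (N_STATES,) or abs(pi.sum() - 1.0) > 1e-8 or (pi <= 0).any():
            raise ModelError("frequencies must be 20 positive values summing to 1")

    @property
    def rates(self) -> np.ndarray:
        """Category rates (length k, equal weights 1/k, mean 1)."""
        return discrete_gamma_rates(self.alpha, self.k)

    @property
    def rate_matrix(self) -> np.ndarray:
        """Normalized rate matrix Q with -sum_i pi_i Q_ii = 1."""
        pi = self.frequencies
        q = self.exchangeabilities * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(pi * np.diag(q)).sum()
        return q / mu

    def _eigen(self):
        """Symmetric eigendecomposition of Q, cached on the instance."""
        if self._eig is None:
            pi = self.frequencies
            sq = np.sqrt(pi)
            b = self.rate_matrix * (sq[:, None] / sq[None, :])
            b = 0.5 * (b + b.T)  # enforce symmetry against round-off
            w, u = np.linalg.eigh(b)
            left = u / sq[:, None]
            right = u.T * sq[None, :]
            object.__setattr__(self, "_eig", (w, left, right))
        return self._eig

    def transition_matrix(self, t: float, rate: float = 1.0) -> np.ndarray:
        """P(t*rate) = exp(Q t rate); rows sum to 1, entries clamped at >= 0."""
        if not np.isfinite(t) or t < 0:
            raise ModelError(f"branch length must be finite and >= 0, got {t}")
        if rate < 0:
            raise ModelError(f"category rate must be >= 0, got {rate}")
        w, left, right = self._eigen()
        p = (left * np.exp(w * (t * rate))) @ right
        np.clip(p, 0.0, None, out=p)
        return p

    def transition_matrices(self, t: float) -> np.ndarray:
        """Stack of P(t * r_c) over the k category rates, shape (k, 20, 20)."""
        if not np.isfinite(t) or t < 0:
            raise ModelError(f"branch length must be finite and >= 0, got {t}")
        w, left, right = self._eigen()
        scale = np.exp(w[None, :] * (t * self.rates[:, None]))  # (k, 20)
        p = np.einsum("ij,cj,jk->cik", left, scale, right)
        np.clip(p, 0.0, None, out=p)
        return p

    def with_alpha(self, alpha: float) -> "SubstitutionModel":
        return replace(self, alpha=float(alpha), _eig=self._eig)

    def with_k(self, k: int) -> "SubstitutionModel":
        return replace(self, k=int(k), _eig=self._eig)

    def spec_string(self) -> str:
        s = self.name
        if self.k > 1:
            s += f"+G{self.k}"
        return s


def empirical_frequencies(alignment) -> np.ndarray:
    """Amino-acid proportions of an alignment ("+F"), missing excluded.

    States with zero counts are floored at a small pseudo-frequency and
    the vector renormalized.
    """
    counts = np.zeros(N_STATES)
    for row in alignment.rows:
        for ch in row:
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ModelError("alignment contains no unambiguous amino acids")
    freqs = counts / total
    freqs = np.maximum(freqs, FREQ_FLOOR)
    return freqs / freqs.sum()


def build_model(
    name: str = "LG",
    k: int = 4,
    alpha: float = 1.0,
    freq_mode: str = "model",
    alignment=None,
) -> SubstitutionModel:
    """Assemble a SubstitutionModel.

    freq_mode "model" uses the table's frequencies; "empirical" ("+F")
    requires an alignment and uses its amino-acid proportions.
    """
    key = name.lower()
    if key == "poisson":
        s = np.full((N_STATES, N_STATES), 1.0)
        np.fill_diagonal(s, 0.0)
        freqs = np.full(N_STATES, 1.0 / N_STATES)
    elif key in ("lg", "wag"):
        s, freqs = _load_table(key)
    else:
        raise ModelError(f"unknown model name {name!r} (expected LG, WAG or Poisson)")
    if freq_mode == "empirical":
        if alignment is None:
            raise ModelError("empirical (+F) frequencies require an alignment")
        freqs = empirical_frequencies(alignment)
    elif freq_mode != "model":
        raise ModelError(f"unknown frequency mode {freq_mode!r}")
    return SubstitutionModel(
        name={"poisson": "Poisson", "lg": "LG", "wag": "WAG"}[key],
        exchangeabilities=s,
        frequencies=freqs,
        alpha=alpha,
        k=k,
    )


_SPEC_RE = re.compile(r"^(LG|WAG|Poisson)(\+G(\d+))?(\+F)?$", re.IGNORECASE)


def parse_model_spec(spec: str, alignment=None, alpha: float = 1.0) -> SubstitutionModel:
    """Parse a model specification string such as "LG+G4+F" or "Poisson".

    Without "+Gk" the model is rate-homogeneous (k=1).
    """
    m = _SPEC_RE.match(spec.strip())
    if not m:
        raise ModelError(f"cannot parse model spec {spec!r}")
    name = m.group(1)
    k = int(m.group(3)) if m.group(3) else 1
    freq_mode = "empirical" if m.group(4) else "model"
    return build_model(name, k=k, alpha=alpha, freq_mode=freq_mode, alignment=alignment)
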