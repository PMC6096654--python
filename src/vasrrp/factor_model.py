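"""Generating/analysis factor models for testlet-based rating formats.

A spec describes a congeneric factor model with simple structure: p items,
each loading on exactly one of L latent traits, with the items additionally
grouped into testlets (one item per trait per testlet, answered jointly on a
single response continuum).  Context effects induced by the joint response
are represented as correlations among the residuals of items sharing a
testlet ("correlated uniqueness").  Two analysis templates follow:

* CT   -- correlated traits, mutually uncorrelated residuals;
* CTCU -- correlated traits, correlated uniqueness within each testlet.

Latent variances are fixed at 1 (correlation metric), so the model-implied
covariance is ``Sigma = Lambda Phi Lambda' + Theta`` with ``Theta`` carrying
the residual variances on its diagonal and, in CTCU mode, the within-testlet
residual covariances off the diagonal.

The module also provides closed-form population oracles (Cronbach's alpha
and composite reliability evaluated on the implied covariance) used to pin
simulation results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "FactorModelSpec",
    "make_4l4i_spec",
    "make_4l8i_spec",
    "circumplex_correlation",
    "implied_covariance",
    "model_degrees_of_freedom",
    "population_alpha",
    "population_composite_reliability",
]

#: Correlation between adjacent traits in the circumplex pattern.
ADJACENT_CORR = 0.3
#: Correlation between non-adjacent (opposite) traits.
OPPOSITE_CORR = 0.1


def circumplex_correlation(n_latents: int = 4) -> np.ndarray:
    """Circumplex correlation pattern: .3 between adjacent traits (cyclic
    neighbours, including the first/last pair), .1 otherwise."""
    R = np.full((n_latents, n_latents), OPPOSITE_CORR)
    for i in range(n_latents):
        R[i, i] = 1.0
        j = (i + 1) % n_latents
        R[i, j] = R[j, i] = ADJACENT_CORR
    return R


def _is_correlation_matrix(R: np.ndarray, *, atol: float = 1e-10) -> bool:
    R = np.asarray(R, float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        return False
    if not np.allclose(R, R.T, atol=atol):
        return False
    if not np.allclose(np.diag(R), 1.0, atol=atol):
        return False
    return bool(np.linalg.eigvalsh(R).min() > atol)


@dataclass
class FactorModelSpec:
    """Full generating model for one simulated scale.

    Items are indexed 0..p-1, grouped by latent trait; ``item_to_latent`` and
    ``item_to_testlet`` map each item to its trait and testlet (both
    0-based).  ``testlet_residual_corr[t]`` is the L x L correlation matrix
    among the residuals of testlet ``t``'s items, ordered by trait index; it
    is ignored (treated as identity) in CT mode.
    """

    loadings: np.ndarray
    item_to_latent: np.ndarray
    item_to_testlet: np.ndarray
    latent_corr: np.ndarray
    residual_vars: np.ndarray
    testlet_residual_corr: np.ndarray
    context_mode: str = "CTCU"
    name: str = field(default="custom")

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, float)
        self.item_to_latent = np.asarray(self.item_to_latent, int)
        self.item_to_testlet = np.asarray(self.item_to_testlet, int)
        self.latent_corr = np.asarray(self.latent_corr, float)
        self.residual_vars = np.asarray(self.residual_vars, float)
        self.testlet_residual_corr = np.asarray(self.testlet_residual_corr, float)
        self.validate()

    # -- basic shape accessors -------------------------------------------
    @property
    def n_items(self) -> int:
        return self.loadings.size

    @property
    def n_latents(self) -> int:
        return self.latent_corr.shape[0]

    @property
    def n_testlets(self) -> int:
        return int(self.item_to_testlet.max()) + 1

    @property
    def n_items_per_latent(self) -> int:
        return self.n_items // self.n_latents

    def items_of_latent(self, latent: int) -> np.ndarray:
        return np.flatnonzero(self.item_to_latent == latent)

    def items_of_testlet(self, testlet: int) -> np.ndarray:
        """Items of one testlet, ordered by their trait index."""
        idx = np.flatnonzero(self.item_to_testlet == testlet)
        return idx[np.argsort(self.item_to_latent[idx])]

    @property
    def lambda_matrix(self) -> np.ndarray:
        """p x L loading matrix with simple structure."""
        Lam = np.zeros((self.n_items, self.n_latents))
        Lam[np.arange(self.n_items), self.item_to_latent] = self.loadings
        return Lam

    def validate(self) -> None:
        p, L, T = self.n_items, self.n_latents, self.n_testlets
        if self.item_to_latent.shape != (p,) or self.item_to_testlet.shape != (p,):
            raise ValueError("item maps must have one entry per item")
        if not _is_correlation_matrix(self.latent_corr):
            raise ValueError("latent_corr must be a positive-definite correlation matrix")
        if np.any(self.residual_vars <= 0):
            raise ValueError("residual variances must be positive")
        if self.context_mode not in ("CT", "CTCU"):
            raise ValueError(f"unknown context_mode {self.context_mode!r}")
        if self.testlet_residual_corr.shape != (T, L, L):
            raise ValueError("need one L x L residual correlation matrix per testlet")
        for t in range(T):
            idx = np.flatnonzero(self.item_to_testlet == t)
            if sorted(self.item_to_latent[idx].tolist()) != list(range(L)):
                raise ValueError(f"testlet {t} must contain exactly one item per latent")
            if self.context_mode == "CTCU" and not _is_correlation_matrix(
                self.testlet_residual_corr[t]
            ):
                raise ValueError(f"testlet {t} residual correlation matrix invalid")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "context_mode": self.context_mode,
            "loadings": self.loadings.tolist(),
            "item_to_latent": self.item_to_latent.tolist(),
            "item_to_testlet": self.item_to_testlet.tolist(),
            "latent_corr": self.latent_corr.tolist(),
            "residual_vars": self.residual_vars.tolist(),
            "testlet_residual_corr": self.testlet_residual_corr.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FactorModelSpec":
        return cls(
            loadings=d["loadings"],
            item_to_latent=d["item_to_latent"],
            item_to_testlet=d["item_to_testlet"],
            latent_corr=d["latent_corr"],
            residual_vars=d["residual_vars"],
            testlet_residual_corr=d["testlet_residual_corr"],
            context_mode=d.get("context_mode", "CTCU"),
            name=d.get("name", "custom"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "FactorModelSpec":
        return cls.from_dict(yaml.safe_load(text))

    def with_mode(self, context_mode: str) -> "FactorModelSpec":
        """Same measurement structure under the other context mode."""
        d = self.to_dict()
        d["context_mode"] = context_mode
        return FactorModelSpec.from_dict(d)


# -- reference specifications ---------------------------------------------

#: Loadings of the 4-latent / 4-items-per-latent reference model, by trait.
LOADINGS_4L4I = (
    (0.65, 0.75, 0.85, 0.95),
    (1.15, 1.05, 0.95, 0.85),
    (0.70, 0.80, 0.90, 1.00),
    (1.20, 1.10, 1.00, 0.90),
)


def _grouped_spec(per_latent_loadings, context_mode: str, name: str) -> FactorModelSpec:
    L = len(per_latent_loadings)
    n_per = len(per_latent_loadings[0])
    loadings = np.concatenate([np.asarray(v, float) for v in per_latent_loadings])
    item_to_latent = np.repeat(np.arange(L), n_per)
    # the j-th item of every trait sits in testlet j
    item_to_testlet = np.tile(np.arange(n_per), L)
    circ = circumplex_correlation(L)
    return FactorModelSpec(
        loadings=loadings,
        item_to_latent=item_to_latent,
        item_to_testlet=item_to_testlet,
        latent_corr=circ,
        residual_vars=np.ones(L * n_per),
        testlet_residual_corr=np.broadcast_to(circ, (n_per, L, L)).copy(),
        context_mode=context_mode,
        name=name,
    )


def make_4l4i_spec(context_mode: str = "CTCU") -> FactorModelSpec:
    """The 4-latent, 4-items-per-latent reference model.

    Four traits in a circumplex (.3 between adjacent traits, .1 otherwise),
    sixteen items in four testlets of one item per trait, unit residual
    variances, and each testlet's residual correlation matrix equal to the
    same circumplex.
    """
    return _grouped_spec(LOADINGS_4L4I, context_mode, "4L4I")


def make_4l8i_spec(context_mode: str = "CTCU") -> FactorModelSpec:
    """The 4-latent, 8-items-per-latent model.

    Loadings run over an evenly spaced grid on [0.60, 1.20] dealt cyclically
    across the four traits, so each trait receives eight loadings spanning
    the same range.
    """
    grid = np.linspace(0.60, 1.20, 32)
    per_latent = [grid[l::4] for l in range(4)]
    return _grouped_spec(per_latent, context_mode, "4L8I")


# -- implied moments and population oracles --------------------------------

def residual_covariance(spec: FactorModelSpec) -> np.ndarray:
    """Theta: residual variances on the diagonal plus, in CTCU mode, the
    within-testlet residual covariances."""
    p = spec.n_items
    sd = np.sqrt(spec.residual_vars)
    Theta = np.diag(spec.residual_vars)
    if spec.context_mode == "CTCU":
        for t in range(spec.n_testlets):
            idx = spec.items_of_testlet(t)
            R = spec.testlet_residual_corr[t]
            Theta[np.ix_(idx, idx)] = R * np.outer(sd[idx], sd[idx])
    return Theta


def implied_covariance(spec: FactorModelSpec) -> np.ndarray:
    """Model-implied covariance ``Sigma = Lambda Phi Lambda' + Theta``."""
    Lam = spec.lambda_matrix
    Sigma = Lam @ spec.latent_corr @ Lam.T + residual_covariance(spec)
    if np.linalg.eigvalsh(Sigma).min() <= 0:
        raise ValueError("implied covariance is not positive definite")
    return Sigma


def model_degrees_of_freedom(
    n_items: int,
    template: str,
    n_latents: int,
    n_testlets: int | None = None,
) -> int:
    """Degrees of freedom of the covariance-structure model.

    Free parameters: p loadings, L(L-1)/2 latent correlations, p residual
    variances, and -- for the CTCU template -- one L(L-1)/2 residual
    correlation block per testlet.  Factor variances are fixed at 1.
    """
    p, L = n_items, n_latents
    q = p + L * (L - 1) // 2 + p
    if template == "CTCU":
        if n_testlets is None:
            raise ValueError("CTCU template requires n_testlets")
        q += n_testlets * L * (L - 1) // 2
    elif template != "CT":
        raise ValueError(f"unknown template {template!r}")
    df = p * (p + 1) // 2 - q
    if df <= 0:
        raise ValueError(f"model is not identified (df = {df})")
    return df


def population_alpha(spec: FactorModelSpec, latent: int) -> float:
    """Cronbach's alpha of one trait's item set, evaluated on the implied
    covariance (the large-sample limit of the sample coefficient)."""
    idx = spec.items_of_latent(latent)
    if idx.size < 2:
        raise ValueError("alpha needs at least two items")
    S = implied_covariance(spec)[np.ix_(idx, idx)]
    k = idx.size
    return k / (k - 1) * (1.0 - np.trace(S) / S.sum())


def population_composite_reliability(spec: FactorModelSpec, latent: int) -> float:
    """Composite reliability rho_c = (sum lambda)^2 / ((sum lambda)^2 + sum var(eps))."""
    idx = spec.items_of_latent(latent)
    s = spec.loadings[idx].sum()
    return s**2 / (s**2 + spec.residual_vars[idx].sum())
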