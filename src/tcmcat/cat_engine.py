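"""Multidimensional graded-response CAT engine.

The severity of each of six syndrome elements is a latent trait. Items follow
Samejima's graded response model (GRM) with between-item multidimensionality:
each item loads on exactly one element, so its Fisher information matrix is
zero outside the (e, e) diagonal entry. Sessions select the next item by the
D-optimality rule — maximize the determinant of the accumulated posterior
information matrix — re-estimate the trait vector by maximum a posteriori
(MAP, Newton-Raphson with step-halving), and stop after a fixed number of
answers (default 20).

Element scores are reported on a T-score-like scale, ``50 + 10 * theta_hat``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import ELEMENTS, N_ELEMENTS

__all__ = [
    "Item",
    "ItemBank",
    "AbilityPrior",
    "CATConfig",
    "CATResult",
    "MapResult",
    "response_probability",
    "item_information",
    "element_information",
    "select_next_item",
    "map_estimate",
    "administer_cat",
    "generate_item_bank",
]


@dataclass(frozen=True)
class Item:
    """One graded-response item loading on a single syndrome element.

    ``thresholds`` are the K-1 ordered category boundaries b_1 < ... < b_{K-1};
    the cumulative probability of responding in category >= k is
    ``expit(a * (theta_e - b_k))``.
    """

    item_id: int
    element_index: int
    discrimination: float
    thresholds: tuple[float, ...]

    def __post_init__(self):
        if not (0 <= self.element_index < N_ELEMENTS):
            raise ValueError(f"element_index out of range: {self.element_index}")
        if not np.isfinite(self.discrimination) or self.discrimination <= 0:
            raise ValueError("discrimination must be a positive finite real")
        b = np.asarray(self.thresholds, dtype=float)
        if b.size < 1 or not np.all(np.isfinite(b)):
            raise ValueError("at least one finite threshold required")
        if not np.all(np.diff(b) > 0):
            raise ValueError("thresholds must be strictly increasing")
        object.__setattr__(self, "discrimination", float(self.discrimination))
        object.__setattr__(self, "thresholds", tuple(float(x) for x in b))

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1


class ItemBank:
    """An indexed collection of items with cached parameter arrays.

    All items must share the same number of categories for the vectorized
    information computation; mixed-K banks are supported through the scalar
    path only.
    """

    def __init__(self, items: Sequence[Item]):
        items = list(items)
        if not items:
            raise ValueError("empty item bank")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError("item_ids must be unique")
        self.items = sorted(items, key=lambda it: it.item_id)
        self.by_id = {it.item_id: it for it in self.items}
        ks = {it.n_categories for it in self.items}
        self._uniform_k = len(ks) == 1
        self._a = np.array([it.discrimination for it in self.items])
        self._elem = np.array([it.element_index for it in self.items])
        self._ids = np.array([it.item_id for it in self.items])
        if self._uniform_k:
            self._b = np.array([it.thresholds for it in self.items], dtype=float)
        else:
            self._b = None

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: int) -> Item:
        return self.by_id[item_id]

    @property
    def item_ids(self) -> np.ndarray:
        return self._ids

    def n_per_element(self) -> np.ndarray:
        return np.bincount(self._elem, minlength=N_ELEMENTS)

    def information_all(self, theta: np.ndarray) -> np.ndarray:
        """Per-item GRM information at theta, for every item in the bank."""
        theta = np.asarray(theta, dtype=float)
        if self._uniform_k:
            a = self._a[:, None]
            th = theta[self._elem][:, None]
            pstar = expit(a * (th - self._b))  # (n, K-1)
            ones = np.ones((len(self.items), 1))
            zeros = np.zeros((len(self.items), 1))
            ps = np.hstack([ones, pstar, zeros])  # cumulative incl. sentinels
            w = ps * (1.0 - ps)
            p = ps[:, :-1] - ps[:, 1:]
            num = (w[:, :-1] - w[:, 1:]) ** 2
            terms = np.where(p > 0, num / np.maximum(p, 1e-300), 0.0)
            return self._a**2 * terms.sum(axis=1)
        return np.array(
            [element_information(it, theta[it.element_index]) for it in self.items]
        )

    # --- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        k_max = max(it.n_categories for it in self.items)
        rows = []
        for it in self.items:
            row = {
                "item_id": it.item_id,
                "element": ELEMENTS[it.element_index],
                "a": it.discrimination,
            }
            for j in range(k_max - 1):
                row[f"b{j + 1}"] = (
                    it.thresholds[j] if j < len(it.thresholds) else np.nan
                )
            rows.append(row)
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemBank":
        b_cols = sorted(
            (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
        items = []
        for _, row in df.iterrows():
            b = [row[c] for c in b_cols if pd.notna(row[c])]
            items.append(
                Item(
                    item_id=int(row["item_id"]),
                    element_index=ELEMENTS.index(row["element"]),
                    discrimination=float(row["a"]),
                    thresholds=tuple(float(x) for x in b),
                )
            )
        return cls(items)

    def to_csv(self, path) -> None:
        # %.17g keeps the binary float round trip exact
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "ItemBank":
        return cls.from_frame(pd.read_csv(path, float_precision="round_trip"))

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "item_id": it.item_id,
                    "element": ELEMENTS[it.element_index],
                    "a": it.discrimination,
                    "b": list(it.thresholds),
                }
                for it in self.items
            ]
        )


@dataclass(frozen=True)
class AbilityPrior:
    """Multivariate normal prior on the six latent severities."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.shape != (N_ELEMENTS,) or cov.shape != (N_ELEMENTS, N_ELEMENTS):
            raise ValueError("prior must be 6-dimensional")
        if not np.allclose(cov, cov.T):
            raise ValueError("covariance must be symmetric")
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance must be positive definite") from exc
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)

    @property
    def precision(self) -> np.ndarray:
        return np.linalg.inv(self.covariance)

    @classmethod
    def standard(cls) -> "AbilityPrior":
        return cls(np.zeros(N_ELEMENTS), np.eye(N_ELEMENTS))


@dataclass(frozen=True)
class CATConfig:
    max_items: int = 20
    selection_rule: str = "d_optimal"  # or "random"
    estimator: str = "map"
    newton_tol: float = 1e-8
    newton_max_iter: int = 100

    def __post_init__(self):
        if self.max_items < 1:
            raise ValueError("max_items must be >= 1")
        if self.selection_rule not in ("d_optimal", "random"):
            raise ValueError(f"unknown selection_rule {self.selection_rule!r}")
        if self.estimator != "map":
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class CATResult:
    theta_hat: np.ndarray
    posterior_se: np.ndarray
    administered: list[int]
    responses: list[int]
    raw_cat_score: np.ndarray
    converged: bool
    trajectory: list[dict] = field(default_factory=list)


@dataclass
class MapResult:
    theta_hat: np.ndarray
    posterior_se: np.ndarray
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# GRM probability machinery
# ---------------------------------------------------------------------------


def _cumulative(item: Item, theta_e: float) -> np.ndarray:
    """P(X >= k) for k = 0..K, with sentinels P(X>=0)=1 and P(X>=K)=0."""
    b = np.asarray(item.thresholds, dtype=float)
    ps = expit(item.discrimination * (theta_e - b))
    return np.concatenate([[1.0], ps, [0.0]])


def response_probability(item: Item, theta: np.ndarray) -> np.ndarray:
    """Category probabilities of a GRM item at trait vector ``theta``.

    Returns a length-K vector summing to 1; category k has probability
    P(X>=k) - P(X>=k+1).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (N_ELEMENTS,) or not np.all(np.isfinite(theta)):
        raise ValueError("theta must be a finite 6-vector")
    ps = _cumulative(item, theta[item.element_index])
    return ps[:-1] - ps[1:]


def element_information(item: Item, theta_e: float) -> float:
    """Unidimensional GRM Fisher information of one item at ``theta_e``."""
    a = item.discrimination
    ps = _cumulative(item, theta_e)
    w = ps * (1.0 - ps)
    p = ps[:-1] - ps[1:]
    num = (w[:-1] - w[1:]) ** 2
    terms = np.where(p > 0, num / np.maximum(p, 1e-300), 0.0)
    return float(a * a * terms.sum())


def item_information(item: Item, theta: np.ndarray) -> np.ndarray:
    """6x6 Fisher information of one item; zero outside its element's diagonal."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (N_ELEMENTS,) or not np.all(np.isfinite(theta)):
        raise ValueError("theta must be a finite 6-vector")
    info = np.zeros((N_ELEMENTS, N_ELEMENTS))
    e = item.element_index
    info[e, e] = element_information(item, theta[e])
    return info


# ---------------------------------------------------------------------------
# Item selection
# ---------------------------------------------------------------------------


def _accumulated_information(
    bank: ItemBank, administered_ids: Sequence[int], theta: np.ndarray, prior: AbilityPrior
) -> np.ndarray:
    A = prior.precision.copy()
    for iid in administered_ids:
        it = bank[iid]
        A[it.element_index, it.element_index] += element_information(
            it, theta[it.element_index]
        )
    return A


def select_next_item(
    bank: ItemBank,
    administered_ids: Sequence[int],
    theta_hat: np.ndarray,
    prior: AbilityPrior,
) -> int:
    """D-optimal selection: maximize det(prior precision + sum of item infos).

    Because a candidate contributes a rank-one update i * e_e e_e^T, the
    determinant equals det(A) * (1 + i * (A^{-1})_{ee}); ranking candidates by
    i * (A^{-1})_{ee} is therefore exactly the determinant ordering. Ties are
    broken by the lowest item_id.
    """
    theta_hat = np.asarray(theta_hat, dtype=float)
    administered = set(administered_ids)
    remaining = [it for it in bank.items if it.item_id not in administered]
    if not remaining:
        raise ValueError("no unadministered items remain in the bank")
    A = _accumulated_information(bank, administered_ids, theta_hat, prior)
    Ainv = np.linalg.inv(A)
    best_id, best_score = None, -np.inf
    for it in remaining:  # bank.items is sorted by item_id -> first max wins
        info = element_information(it, theta_hat[it.element_index])
        score = info * Ainv[it.element_index, it.element_index]
        if score > best_score:
            best_id, best_score = it.item_id, score
    return best_id


def _select_fast(
    bank: ItemBank,
    remaining_mask: np.ndarray,
    theta_hat: np.ndarray,
    Ainv: np.ndarray,
) -> int:
    infos = bank.information_all(theta_hat)
    scores = infos * Ainv[bank._elem, bank._elem]
    scores = np.where(remaining_mask, scores, -np.inf)
    return int(bank._ids[int(np.argmax(scores))])  # argmax -> first max = lowest id


# ---------------------------------------------------------------------------
# MAP estimation
# ---------------------------------------------------------------------------


def _response_arrays(items: Sequence[Item], responses: Sequence[int]):
    """Per-response (a, element, lower/upper cumulative threshold) arrays.

    For response category k the likelihood term is
    P(X>=k) - P(X>=k+1) = expit(a (theta - lo)) - expit(a (theta - hi)),
    with lo = -inf for k = 0 and hi = +inf for k = K-1.
    """
    m = len(items)
    a = np.empty(m)
    e = np.empty(m, dtype=int)
    lo = np.empty(m)
    hi = np.empty(m)
    for j, (it, k) in enumerate(zip(items, responses)):
        if not (0 <= k < it.n_categories):
            raise ValueError(
                f"response {k} out of range for item {it.item_id} "
                f"with {it.n_categories} categories"
            )
        a[j] = it.discrimination
        e[j] = it.element_index
        lo[j] = it.thresholds[k - 1] if k >= 1 else -np.inf
        hi[j] = it.thresholds[k] if k < it.n_categories - 1 else np.inf
    return a, e, lo, hi


def _loglik_terms(a, e, lo, hi, theta):
    th = theta[e]
    plo = expit(a * (th - lo))
    phi = expit(a * (th - hi))
    p = np.maximum(plo - phi, 1e-300)
    ulo = a * plo * (1.0 - plo)
    uhi = a * phi * (1.0 - phi)
    dp = ulo - uhi
    d2p = a * a * (
        plo * (1.0 - plo) * (1.0 - 2.0 * plo) - phi * (1.0 - phi) * (1.0 - 2.0 * phi)
    )
    dlog = dp / p
    d2log = d2p / p - dlog * dlog
    return np.log(p), dlog, d2log


def map_estimate(
    items: Sequence[Item],
    responses: Sequence[int],
    prior: AbilityPrior,
    config: CATConfig | None = None,
) -> MapResult:
    """Maximum a posteriori trait estimate with Newton-Raphson.

    Starts at the prior mean; converges when the gradient 2-norm falls below
    ``newton_tol``. Step-halving guards against log-posterior decreases (the
    GRM log-likelihood is concave, so the full Newton step almost always
    suffices). The posterior SE is the square root of the diagonal of the
    inverse negative Hessian at the mode; with no items answered this reduces
    to the prior SD exactly.
    """
    config = config or CATConfig()
    if len(items) != len(responses):
        raise ValueError("items and responses must align")
    prec = prior.precision
    mean = prior.mean
    if not items:
        return MapResult(mean.copy(), np.sqrt(np.diag(prior.covariance)), True, 0)

    a, e, lo, hi = _response_arrays(items, responses)
    theta = mean.copy()

    def log_posterior(th):
        logp, _, _ = _loglik_terms(a, e, lo, hi, th)
        dev = th - mean
        return logp.sum() - 0.5 * dev @ prec @ dev

    converged = False
    n_iter = 0
    lp = log_posterior(theta)
    for n_iter in range(1, config.newton_max_iter + 1):
        logp, dlog, d2log = _loglik_terms(a, e, lo, hi, theta)
        grad = np.bincount(e, weights=dlog, minlength=N_ELEMENTS) - prec @ (theta - mean)
        if np.linalg.norm(grad) < config.newton_tol:
            converged = True
            break
        H = prec - np.diag(np.bincount(e, weights=d2log, minlength=N_ELEMENTS))
        step = np.linalg.solve(H, grad)
        new_theta = theta + step
        new_lp = log_posterior(new_theta)
        halvings = 0
        while new_lp < lp and halvings < 30:
            step *= 0.5
            new_theta = theta + step
            new_lp = log_posterior(new_theta)
            halvings += 1
        theta, lp = new_theta, new_lp

    _, _, d2log = _loglik_terms(a, e, lo, hi, theta)
    H = prec - np.diag(np.bincount(e, weights=d2log, minlength=N_ELEMENTS))
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return MapResult(theta, se, converged, n_iter)


# ---------------------------------------------------------------------------
# Adaptive session
# ---------------------------------------------------------------------------


def _simulate_response(item: Item, true_theta: np.ndarray, rng: np.random.Generator) -> int:
    probs = response_probability(item, true_theta)
    return int(np.searchsorted(np.cumsum(probs), rng.random()))


def administer_cat(
    bank: ItemBank,
    true_theta: np.ndarray | None = None,
    config: CATConfig | None = None,
    prior: AbilityPrior | None = None,
    rng: np.random.Generator | None = None,
    response_oracle: Callable[[Item], int] | None = None,
) -> CATResult:
    """Run one adaptive session: select, respond, re-estimate, stop at max_items.

    Responses are simulated from ``true_theta`` under the GRM unless a
    ``response_oracle`` callable is supplied. Reported element scores are
    ``50 + 10 * theta_hat``.
    """
    config = config or CATConfig()
    prior = prior or AbilityPrior.standard()
    rng = rng or np.random.default_rng()
    if config.max_items > len(bank):
        raise ValueError("max_items exceeds bank size")
    if true_theta is None and response_oracle is None:
        raise ValueError("either true_theta or response_oracle is required")
    if true_theta is not None:
        true_theta = np.asarray(true_theta, dtype=float)

    remaining = np.ones(len(bank), dtype=bool)
    id_to_pos = {iid: j for j, iid in enumerate(bank.item_ids)}
    A = prior.precision.copy()
    theta = prior.mean.copy()
    administered: list[int] = []
    responses: list[int] = []
    answered_items: list[Item] = []
    trajectory: list[dict] = []
    est = MapResult(theta, np.sqrt(np.diag(prior.covariance)), True, 0)

    for _ in range(config.max_items):
        if config.selection_rule == "d_optimal":
            iid = _select_fast(bank, remaining, theta, np.linalg.inv(A))
        else:
            pool = bank.item_ids[remaining]
            iid = int(rng.choice(pool))
        item = bank[iid]
        if response_oracle is not None:
            resp = int(response_oracle(item))
        else:
            resp = _simulate_response(item, true_theta, rng)
        administered.append(iid)
        responses.append(resp)
        answered_items.append(item)
        remaining[id_to_pos[iid]] = False

        est = map_estimate(answered_items, responses, prior, config)
        theta = est.theta_hat
        A = _accumulated_information(bank, administered, theta, prior)
        trajectory.append(
            {
                "item_id": iid,
                "response": resp,
                "theta_hat": theta.tolist(),
                "posterior_se": est.posterior_se.tolist(),
            }
        )

    return CATResult(
        theta_hat=theta,
        posterior_se=est.posterior_se,
        administered=administered,
        responses=responses,
        raw_cat_score=50.0 + 10.0 * theta,
        converged=est.converged,
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# Synthetic item bank
# ---------------------------------------------------------------------------


def generate_item_bank(
    n_items: int = 215,
    n_elements: int = N_ELEMENTS,
    n_categories: int = 5,
    seed: int | np.random.Generator = 0,
    meanlog: float = 0.2,
    sdlog: float = 0.3,
) -> ItemBank:
    """Simulate a calibrated bank: round-robin element allocation, log-normal
    discriminations, per-element-centred ordered thresholds.

    The default size (215) mirrors the scale of a realistic multidimensional
    symptom bank; each element receives 35 or 36 items.
    """
    if n_items < n_elements:
        raise ValueError("need at least one item per element")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    centers = rng.normal(0.0, 0.3, size=n_elements)
    items = []
    for i in range(n_items):
        e = i % n_elements
        a = float(rng.lognormal(meanlog, sdlog))
        b = np.sort(rng.normal(centers[e], 1.0, size=n_categories - 1))
        for k in range(1, b.size):  # enforce strict increase with a floor gap
            b[k] = max(b[k], b[k - 1] + 0.05)
        items.append(Item(item_id=i + 1, element_index=e, discrimination=a, thresholds=tuple(b)))
    return ItemBank(items)
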