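"""GA-BP-GA surrogate inversion of bond parameters.

A small feed-forward network (4 inputs -> S tansig hidden units -> 1 linear
output) is trained to map the four calibrated bond parameters (K_n, K_s,
tau_m, R_ab) to the peak compression force.  A real-coded genetic algorithm
seeds the network weights, gradient training refines them, and a second
genetic algorithm then inverts the trained surrogate: it searches the
physical parameter box for settings whose predicted force matches the
laboratory target.

Inputs and the response are normalised column-wise to [-1, 1]
(mapminmax-style) before training; the trained net stores its ranges and
accepts physical units.

The default trainer is Levenberg–Marquardt with the analytic Jacobian of
the 4-S-1 net: on data sets of this size it reaches the target error within
a handful of epochs, which is the observed behaviour of the reference
workflow.  A plain gradient-descent-with-momentum trainer is available as
``trainer="gdm"``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .doe import CCD_FACTORS, DesignMatrix, FactorDef, QuadraticModel

__all__ = [
    "SurrogateConfig",
    "GAConfig",
    "TrainingSet",
    "Normalizer",
    "SurrogateNet",
    "hidden_node_candidates",
    "training_set_from_quadratic_grid",
    "training_set_from_design_repeats",
    "train_bpnn",
    "ga_optimize",
    "select_hidden_nodes",
    "invert_surrogate",
]


# ----------------------------------------------------------- configuration


@dataclass(frozen=True)
class SurrogateConfig:
    """Network and training settings (4-S-1 architecture)."""

    n_inputs: int = 4
    n_outputs: int = 1
    hidden_nodes: int = 13
    lr: float = 0.001
    target_error: float = 0.001
    max_epochs: int = 200
    train_fraction: float = 0.7
    trainer: str = "lm"  # "lm" or "gdm"
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self):
        if not 4 <= self.hidden_nodes <= 13:
            raise ValueError("hidden_nodes must lie in [4, 13]")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.trainer not in ("lm", "gdm"):
            raise ValueError("trainer must be 'lm' or 'gdm'")


@dataclass(frozen=True)
class GAConfig:
    """Real-coded genetic algorithm settings.

    ``selection_pressure`` is the probability-of-best of normalised
    geometric ranking selection; crossover is arithmetic blending applied at
    ``crossover_rate``; mutation resamples one gene of an individual
    uniformly within bounds at ``mutation_rate``.
    """

    generations: int = 200
    population: int = 200
    selection_pressure: float = 0.09
    crossover_rate: float = 0.8
    mutation_rate: float = 0.2
    bounds: tuple[np.ndarray, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self):
        for r in (self.selection_pressure, self.mutation_rate):
            if not 0 < r <= 1:
                raise ValueError("GA rates must lie in (0, 1]")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.population % 2:
            raise ValueError("population must be even")


def hidden_node_candidates(n_inputs: int = 4, n_outputs: int = 1) -> range:
    """Candidate hidden-layer sizes ceil(sqrt(n + l)) + c for c = 1..10."""
    base = math.ceil(math.sqrt(n_inputs + n_outputs))
    return range(base + 1, base + 11)


# ------------------------------------------------------------- normalising


@dataclass(frozen=True)
class Normalizer:
    """Column-wise affine map onto [-1, 1] with exact inverse."""

    lo: np.ndarray
    hi: np.ndarray

    @staticmethod
    def fit(data: np.ndarray) -> "Normalizer":
        data = np.atleast_2d(np.asarray(data, float))
        lo, hi = data.min(axis=0), data.max(axis=0)
        if np.any(hi - lo <= 0):
            raise ValueError("cannot normalise a constant column")
        return Normalizer(lo=lo, hi=hi)

    def forward(self, data):
        return 2.0 * (np.asarray(data, float) - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, scaled):
        return self.lo + (np.asarray(scaled, float) + 1.0) * (self.hi - self.lo) / 2.0


# ------------------------------------------------------------ training set


@dataclass
class TrainingSet:
    """Physical-unit inputs (n, 4) and responses (n,), with a seeded
    70/30 train/test split."""

    inputs: np.ndarray
    responses: np.ndarray
    factors: tuple[FactorDef, ...] = tuple(CCD_FACTORS)

    def __post_init__(self):
        self.inputs = np.asarray(self.inputs, float)
        self.responses = np.asarray(self.responses, float).ravel()
        if len(self.inputs) != len(self.responses):
            raise ValueError("inputs and responses must have equal length")

    def split(self, fraction: float, seed: int):
        n = len(self.responses)
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        n_train = int(round(fraction * n))
        return perm[:n_train], perm[n_train:]


def training_set_from_quadratic_grid(
    model: QuadraticModel, levels=(-1.0, 0.0, 1.0)
) -> TrainingSet:
    """Noiseless responses of a fitted response surface over the full coded
    grid (3^4 = 81 points for three levels)."""
    import itertools

    coded = np.array(list(itertools.product(levels, repeat=len(model.factors))))
    phys = np.column_stack(
        [f.decode(coded[:, j]) for j, f in enumerate(model.factors)]
    )
    return TrainingSet(
        inputs=phys,
        responses=model.predict_coded(coded),
        factors=tuple(model.factors),
    )


def training_set_from_design_repeats(
    design: DesignMatrix, n_repeats: int = 3, noise_sd: float = 181.8, seed: int = 0
) -> TrainingSet:
    """Expand run-mean responses of a design into per-repeat samples.

    Individual repeats are synthesised by adding Gaussian noise at the
    design's pure-error standard deviation around each run mean (27 runs x 3
    repeats = 81 samples for the calibration CCD).
    """
    if design.responses is None:
        raise ValueError("design has no responses")
    rng = np.random.default_rng(seed)
    phys = design.to_physical()[design.names].to_numpy()
    X = np.repeat(phys, n_repeats, axis=0)
    y = np.repeat(design.responses, n_repeats) + noise_sd * rng.standard_normal(
        len(design.responses) * n_repeats
    )
    return TrainingSet(inputs=X, responses=y, factors=tuple(design.factors))


# -------------------------------------------------------------------- net


@dataclass
class SurrogateNet:
    """Trained 4-S-1 network with embedded normalisation ranges."""

    W1: np.ndarray  # (S, n_in)
    b1: np.ndarray  # (S,)
    w2: np.ndarray  # (S,)
    b2: float
    x_norm: Normalizer
    y_norm: Normalizer

    @property
    def hidden_nodes(self) -> int:
        return len(self.b1)

    def forward_normalized(self, Xn: np.ndarray) -> np.ndarray:
        Xn = np.atleast_2d(Xn)
        return np.tanh(Xn @ self.W1.T + self.b1) @ self.w2 + self.b2

    def predict(self, X_physical: np.ndarray) -> np.ndarray:
        """Peak force (N) for physical-unit bond parameters (n, 4)."""
        Xn = self.x_norm.forward(np.atleast_2d(X_physical))
        yn = self.forward_normalized(Xn)
        return self.y_norm.inverse(yn[:, None]).ravel()

    # -- weight vector packing (GA / LM work on flat vectors) ----------
    def pack(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.w2, [self.b2]])

    @staticmethod
    def n_weights(S: int, n_in: int = 4) -> int:
        return S * n_in + S + S + 1

    @staticmethod
    def unpack(theta: np.ndarray, S: int, n_in: int,
               x_norm: Normalizer, y_norm: Normalizer) -> "SurrogateNet":
        i = 0
        W1 = theta[i : i + S * n_in].reshape(S, n_in); i += S * n_in
        b1 = theta[i : i + S]; i += S
        w2 = theta[i : i + S]; i += S
        b2 = float(theta[i])
        return SurrogateNet(W1, b1, w2, b2, x_norm, y_norm)

    def to_json(self, path) -> None:
        obj = {
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "x_lo": self.x_norm.lo.tolist(),
            "x_hi": self.x_norm.hi.tolist(),
            "y_lo": self.y_norm.lo.tolist(),
            "y_hi": self.y_norm.hi.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @staticmethod
    def from_json(path) -> "SurrogateNet":
        with open(path) as fh:
            o = json.load(fh)
        return SurrogateNet(
            np.array(o["W1"]), np.array(o["b1"]), np.array(o["w2"]), o["b2"],
            Normalizer(np.array(o["x_lo"]), np.array(o["x_hi"])),
            Normalizer(np.array(o["y_lo"]), np.array(o["y_hi"])),
        )


def _batch_forward(thetas: np.ndarray, S: int, n_in: int, Xn: np.ndarray) -> np.ndarray:
    """Network outputs for a population of weight vectors: (P, n_samples)."""
    P = thetas.shape[0]
    i = 0
    W1 = thetas[:, : S * n_in].reshape(P, S, n_in); i = S * n_in
    b1 = thetas[:, i : i + S]; i += S
    w2 = thetas[:, i : i + S]; i += S
    b2 = thetas[:, i]
    H = np.tanh(np.einsum("psd,nd->pns", W1, Xn) + b1[:, None, :])
    return np.einsum("pns,ps->pn", H, w2) + b2[:, None]


# --------------------------------------------------------------- trainers


def _lm_train(theta, S, n_in, Xn, yn, target_error, max_epochs):
    """Levenberg–Marquardt on the residuals of the 4-S-1 net."""
    n = len(yn)

    def forward_parts(th):
        W1 = th[: S * n_in].reshape(S, n_in)
        b1 = th[S * n_in : S * n_in + S]
        w2 = th[S * n_in + S : S * n_in + 2 * S]
        b2 = th[-1]
        A = Xn @ W1.T + b1
        H = np.tanh(A)
        return W1, b1, w2, b2, H

    def mse_of(th):
        *_, w2, b2, H = forward_parts(th)
        return float(((H @ w2 + b2 - yn) ** 2).mean())

    lam = 1e-2
    mse = mse_of(theta)
    trace = [mse]
    for _ in range(max_epochs):
        if mse <= target_error:
            break
        W1, b1, w2, b2, H = forward_parts(theta)
        resid = H @ w2 + b2 - yn
        dH = (1.0 - H * H) * w2  # (n, S)
        J = np.concatenate(
            [
                (dH[:, :, None] * Xn[:, None, :]).reshape(n, S * n_in),
                dH,
                H,
                np.ones((n, 1)),
            ],
            axis=1,
        )
        g = J.T @ resid
        JtJ = J.T @ J
        accepted = False
        for _try in range(12):
            try:
                step = np.linalg.solve(JtJ + lam * np.eye(len(theta)), g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            cand = theta - step
            m = mse_of(cand)
            if np.isfinite(m) and m < mse:
                theta, mse = cand, m
                lam = max(lam / 10.0, 1e-12)
                accepted = True
                break
            lam *= 10.0
        trace.append(mse)
        if not accepted:
            break
    return theta, np.array(trace)


def _gdm_train(theta, S, n_in, Xn, yn, lr, momentum, target_error, max_epochs):
    """Full-batch gradient descent with momentum."""
    vel = np.zeros_like(theta)
    n = len(yn)
    trace = []
    err = np.errstate(over="ignore", invalid="ignore")
    err.__enter__()
    for _ in range(max_epochs):
        W1 = theta[: S * n_in].reshape(S, n_in)
        b1 = theta[S * n_in : S * n_in + S]
        w2 = theta[S * n_in + S : S * n_in + 2 * S]
        b2 = theta[-1]
        H = np.tanh(Xn @ W1.T + b1)
        resid = H @ w2 + b2 - yn
        mse = float((resid**2).mean())
        trace.append(mse)
        if mse <= target_error:
            break
        dH = (1.0 - H * H) * w2
        grad = np.concatenate(
            [
                ((resid[:, None] * dH)[:, :, None] * Xn[:, None, :]).sum(0).ravel(),
                (resid[:, None] * dH).sum(0),
                H.T @ resid,
                [resid.sum()],
            ]
        ) * (2.0 / n)
        if not np.all(np.isfinite(grad)):
            raise FloatingPointError("gradient training diverged (NaN loss)")
        vel = momentum * vel - lr * grad
        theta = theta + vel
    err.__exit__(None, None, None)
    return theta, np.array(trace)


# --------------------------------------------------------------------- GA


def ga_optimize(fitness, cfg: GAConfig):
    """Minimise ``fitness`` with a real-coded GA.

    ``fitness`` maps a population array (P, n) to (P,) costs (a scalar
    function of one vector is also accepted).  Selection is normalised
    geometric ranking with probability-of-best ``selection_pressure``;
    crossover is arithmetic blending; mutation resamples one gene uniformly
    within bounds.  The best-ever individual is elitist-preserved, so the
    best cost trace is non-increasing.  Fully deterministic for a fixed
    seed.
    """
    if cfg.bounds is None:
        raise ValueError("GAConfig.bounds is required")
    lo, hi = (np.asarray(b, float) for b in cfg.bounds)
    if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
        raise ValueError("GA bounds must be finite")
    n = len(lo)
    rng = np.random.default_rng(cfg.seed)
    P = cfg.population

    def evaluate(X):
        try:
            f = np.asarray(fitness(X), float)
            if f.shape != (len(X),):
                raise TypeError
        except TypeError:
            f = np.array([float(fitness(x)) for x in X])
        return f

    pop = lo + (hi - lo) * rng.random((P, n))
    cost = evaluate(pop)
    best_i = int(np.argmin(cost))
    best_x, best_f = pop[best_i].copy(), float(cost[best_i])
    trace = [best_f]

    q = cfg.selection_pressure
    ranks = np.arange(P)
    sel_p = q * (1.0 - q) ** ranks
    sel_p /= sel_p.sum()

    for _ in range(cfg.generations):
        order = np.argsort(cost)
        parents_idx = order[rng.choice(P, size=P, p=sel_p)]
        parents = pop[parents_idx]
        children = parents.copy()
        for i in range(0, P, 2):
            if rng.random() < cfg.crossover_rate:
                a = rng.random()
                p1, p2 = parents[i], parents[i + 1]
                children[i] = a * p1 + (1 - a) * p2
                children[i + 1] = (1 - a) * p1 + a * p2
        mutate = rng.random(P) < cfg.mutation_rate
        for i in np.where(mutate)[0]:
            g = rng.integers(n)
            children[i, g] = lo[g] + (hi[g] - lo[g]) * rng.random()
        np.clip(children, lo, hi, out=children)
        children[0] = best_x  # elitism
        pop = children
        cost = evaluate(pop)
        i = int(np.argmin(cost))
        if cost[i] < best_f:
            best_x, best_f = pop[i].copy(), float(cost[i])
        trace.append(best_f)

    return {"x": best_x, "fun": best_f, "trace": np.array(trace)}


# ----------------------------------------------------------- orchestration


def train_bpnn(
    ts: TrainingSet,
    cfg: SurrogateConfig = SurrogateConfig(),
    init_weights: np.ndarray | None = None,
    ga_init: bool = True,
    ga_cfg: GAConfig | None = None,
) -> tuple[SurrogateNet, dict]:
    """Train the surrogate network on a training set.

    By default a GA (population/generations per ``ga_cfg``) first minimises
    the training MSE over the flat weight vector, then the gradient trainer
    refines the best individual until ``target_error`` or ``max_epochs``.
    Returns the net plus a report with train/test MSE and correlation.
    """
    S, n_in = cfg.hidden_nodes, cfg.n_inputs
    x_norm = Normalizer.fit(ts.inputs)
    y_norm = Normalizer.fit(ts.responses[:, None])
    Xn = x_norm.forward(ts.inputs)
    yn = y_norm.forward(ts.responses[:, None]).ravel()
    itr, ite = ts.split(cfg.train_fraction, cfg.seed)
    Xtr, ytr = Xn[itr], yn[itr]
    Xte, yte = Xn[ite], yn[ite]

    n_w = SurrogateNet.n_weights(S, n_in)
    if init_weights is not None:
        theta = np.asarray(init_weights, float).copy()
        if theta.shape != (n_w,):
            raise ValueError(f"init_weights must have shape ({n_w},)")
    elif ga_init:
        gcfg = ga_cfg or GAConfig(bounds=(-np.ones(n_w), np.ones(n_w)), seed=cfg.seed)
        if gcfg.bounds is None:
            gcfg = replace(gcfg, bounds=(-np.ones(n_w), np.ones(n_w)))

        def weight_fitness(pop):
            pred = _batch_forward(pop, S, n_in, Xtr)
            return ((pred - ytr) ** 2).mean(axis=1)

        theta = ga_optimize(weight_fitness, gcfg)["x"]
    else:
        rng = np.random.default_rng(cfg.seed)
        theta = rng.uniform(-1, 1, n_w)

    if cfg.trainer == "lm":
        theta, trace = _lm_train(theta, S, n_in, Xtr, ytr,
                                 cfg.target_error, cfg.max_epochs)
    else:
        theta, trace = _gdm_train(theta, S, n_in, Xtr, ytr, cfg.lr, cfg.momentum,
                                  cfg.target_error, cfg.max_epochs)
    if not np.all(np.isfinite(theta)):
        raise FloatingPointError(f"training diverged (seed={cfg.seed})")

    net = SurrogateNet.unpack(theta, S, n_in, x_norm, y_norm)
    pred_tr = net.forward_normalized(Xtr)
    pred_te = net.forward_normalized(Xte)
    report = {
        "train_mse": float(((pred_tr - ytr) ** 2).mean()),
        "test_mse": float(((pred_te - yte) ** 2).mean()) if len(yte) else np.nan,
        "train_r": _pearson(pred_tr, ytr),
        "test_r": _pearson(pred_te, yte) if len(yte) > 1 else np.nan,
        "epochs": len(trace) - 1,
        "mse_trace": trace,
        "n_train": len(itr),
        "n_test": len(ite),
    }
    return net, report


def _pearson(a, b) -> float:
    if len(a) < 2 or np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def select_hidden_nodes(
    ts: TrainingSet,
    cfg: SurrogateConfig = SurrogateConfig(),
    candidates=None,
    repeats: int = 5,
    ga_cfg: GAConfig | None = None,
) -> tuple[int, "np.ndarray"]:
    """Pick the hidden-layer size with the lowest mean validation MSE.

    Each candidate is trained ``repeats`` times with distinct seeds (fresh
    splits and initialisations); returns the argmin candidate and the full
    (candidate, repeat) MSE table.
    """
    if candidates is None:
        candidates = list(hidden_node_candidates(cfg.n_inputs, cfg.n_outputs))
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    table = np.zeros((len(candidates), repeats))
    for i, S in enumerate(candidates):
        for rep in range(repeats):
            c = replace(cfg, hidden_nodes=S, seed=cfg.seed + 1000 * rep + S)
            _, rpt = train_bpnn(ts, c, ga_cfg=ga_cfg)
            table[i, rep] = rpt["test_mse"]
    best = candidates[int(np.argmin(table.mean(axis=1)))]
    return best, table


def invert_surrogate(
    net: SurrogateNet,
    target: float,
    cfg: GAConfig | None = None,
) -> dict:
    """GA inversion of the trained surrogate to a target force.

    Minimises ``|prediction - target|`` over the physical parameter box
    (default: the calibration bounds embedded in the net's normalisation
    ranges).  Returns the physical solution, its predicted force and the
    fitness trace.
    """
    if cfg is None:
        cfg = GAConfig(
            generations=100,
            population=200,
            selection_pressure=0.8,
            crossover_rate=1.0,
            mutation_rate=0.2,
            bounds=(net.x_norm.lo.copy(), net.x_norm.hi.copy()),
        )
    if cfg.bounds is None:
        cfg = replace(cfg, bounds=(net.x_norm.lo.copy(), net.x_norm.hi.copy()))

    def fitness(pop):
        return np.abs(net.predict(pop) - target)

    res = ga_optimize(fitness, cfg)
    return {
        "params": res["x"],
        "predicted": float(net.predict(res["x"][None, :])[0]),
        "target": target,
        "trace": res["trace"],
    }
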