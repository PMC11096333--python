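"""Inference: paired/one-sample t with dz, JZS Bayes factors, time-axis
cluster-based permutation testing, and noncentral-t power analysis.

The Bayes factor is the default one-sample/paired JZS ratio: marginal
likelihood of the t statistic under a Cauchy(0, r) prior on the standardized
effect, evaluated by adaptive quadrature over the effect size, divided by
the likelihood under the point null.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import integrate
from scipy import stats as sps

TAILS = ("two", "greater", "less")


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    dz: float
    n: int
    tail: str = "two"

    def __post_init__(self) -> None:
        if self.df != self.n - 1:
            raise StatsError("df must equal n - 1")


@dataclass(frozen=True)
class BayesFactorResult:
    bf10: float
    t: float
    n: int
    r: float = 0.707

    @property
    def bf01(self) -> float:
        return 1.0 / self.bf10


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    t_sum: float
    p_perm: float


@dataclass
class ClusterResult:
    clusters: list[Cluster]
    n_permutations: int
    cluster_alpha: float
    seed: int
    t_threshold: float

    def significant(self, alpha: float = 0.05) -> list[Cluster]:
        return [c for c in self.clusters if c.p_perm < alpha]


@dataclass(frozen=True)
class PowerResult:
    n_required: int
    dz: float
    alpha: float
    power: float
    achieved_power: float


def _p_from_t(t: float, df: int, tail: str) -> float:
    if tail == "two":
        return 2.0 * sps.t.sf(abs(t), df)
    if tail == "greater":
        return float(sps.t.sf(t, df))
    if tail == "less":
        return float(sps.t.cdf(t, df))
    raise StatsError(f"unknown tail {tail!r}")


def one_sample_t_dz(x, mu: float = 0.0, tail: str = "two") -> TTestResult:
    """One-sample t-test of ``x`` against ``mu``, with dz = mean/sd."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise StatsError("need a 1-D sample of length >= 2")
    if np.any(np.isnan(x)):
        raise StatsError("missing values are not allowed")
    d = x - mu
    sd = d.std(ddof=1)
    n = len(d)
    if sd == 0:
        if np.all(d == 0):
            # identical samples: defined as no effect, no evidence
            return TTestResult(0.0, n - 1, 1.0, 0.0, n, tail)
        raise StatsError("zero-variance sample")
    dz = d.mean() / sd
    t = dz * np.sqrt(n)
    return TTestResult(float(t), n - 1, _p_from_t(t, n - 1, tail), float(dz),
                       n, tail)


def paired_t_dz(x, y, tail: str = "two") -> TTestResult:
    """Paired t-test on per-participant differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("paired samples must have equal length")
    return one_sample_t_dz(x - y, 0.0, tail)


def dz_from_t(t: float, n: int) -> float:
    """Standardized within-participant effect size from a t statistic."""
    return t / np.sqrt(n)


def jzs_bf10(t: float, n: int, r: float = 0.707) -> BayesFactorResult:
    """Default JZS Bayes factor (alternative vs point null) for a
    one-sample/paired design.

    BF10 = integral over delta of T_df(t; ncp = delta*sqrt(n)) *
    Cauchy(delta; 0, r) d delta, divided by T_df(t; 0).
    """
    if n < 2:
        raise StatsError("n must be >= 2")
    if r <= 0:
        raise StatsError("prior scale r must be positive")
    df = n - 1
    root_n = np.sqrt(n)

    def integrand(delta):
        return (sps.nct.pdf(t, df, delta * root_n)
                * sps.cauchy.pdf(delta, 0.0, r))

    num = 0.0
    err = 0.0
    # split at 0 and at the MLE so quadrature sees the mass
    knots = sorted({-np.inf, 0.0, t / root_n, np.inf})
    for lo, hi in zip(knots[:-1], knots[1:]):
        val, e = integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=1e-9,
                                limit=400)
        num += val
        err += e
    if num <= 0 or not np.isfinite(num) or err > 1e-6 * num:
        raise StatsError(f"Bayes factor quadrature failed "
                         f"(value={num}, err={err})")
    den = sps.t.pdf(t, df)
    return BayesFactorResult(float(num / den), float(t), int(n), float(r))


def _cluster_runs(tvals: np.ndarray, threshold: float
                  ) -> list[tuple[int, int, float]]:
    """Maximal contiguous runs of same-sign suprathreshold t values."""
    out = []
    sign = np.where(tvals > threshold, 1, np.where(tvals < -threshold, -1, 0))
    i = 0
    n = len(sign)
    while i < n:
        if sign[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and sign[j + 1] == sign[i]:
            j += 1
        out.append((i, j, float(tvals[i:j + 1].sum())))
        i = j + 1
    return out


def _pointwise_t(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    m = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    sd[sd == 0] = np.inf
    return m / (sd / np.sqrt(n))


def cluster_permutation(
    series_a: np.ndarray,
    series_b: np.ndarray,
    time_axis: np.ndarray,
    n_permutations: int = 10_000,
    cluster_alpha: float = 0.05,
    tail: str = "two",
    seed: int = 0,
) -> ClusterResult:
    """Paired cluster-based permutation test along the time axis.

    Pointwise paired t values are thresholded at the critical t for
    *cluster_alpha* (two-tailed by default); maximal contiguous same-sign
    runs are summarized by their summed t (t_sum); the null distribution of
    the maximum |t_sum| is built from random per-participant sign flips of
    the difference series; each observed cluster gets
    p = (1 + #{null >= |t_sum|}) / (1 + n_permutations).
    """
    a = np.atleast_2d(np.asarray(series_a, dtype=float))
    b = np.atleast_2d(np.asarray(series_b, dtype=float))
    t_axis = np.asarray(time_axis, dtype=float)
    if a.shape != b.shape or a.shape[1] != len(t_axis):
        raise StatsError("mismatched participants or time axes")
    n = a.shape[0]
    if n < 2:
        raise StatsError("need at least 2 participants")
    if tail not in TAILS:
        raise StatsError(f"unknown tail {tail!r}")
    diff = a - b
    if tail == "two":
        threshold = float(sps.t.ppf(1.0 - cluster_alpha / 2.0, n - 1))
    else:
        threshold = float(sps.t.ppf(1.0 - cluster_alpha, n - 1))
    tvals = _pointwise_t(diff)
    runs = _cluster_runs(tvals, threshold)
    if tail == "greater":
        runs = [r for r in runs if r[2] > 0]
    elif tail == "less":
        runs = [r for r in runs if r[2] < 0]

    rng = np.random.default_rng(seed)
    sq_mean = (diff ** 2).mean(axis=0)
    null_max = np.zeros(n_permutations)
    chunk = max(1, min(n_permutations, 20_000_000 // max(diff.size, 1)))
    done = 0
    while done < n_permutations:
        k = min(chunk, n_permutations - done)
        signs = rng.choice([-1.0, 1.0], size=(k, n))
        means = signs @ diff / n                          # (k, T)
        var = (sq_mean[None, :] - means ** 2) * n / (n - 1)
        var[var <= 0] = np.inf
        t_perm = means / np.sqrt(var / n)
        for row in t_perm:
            perm_runs = _cluster_runs(row, threshold)
            null_max[done] = max((abs(r[2]) for r in perm_runs), default=0.0)
            done += 1

    clusters = []
    for i, j, t_sum in runs:
        p = (1.0 + np.sum(null_max >= abs(t_sum))) / (1.0 + n_permutations)
        clusters.append(Cluster(float(t_axis[i]), float(t_axis[j]),
                                t_sum, float(p)))
    clusters.sort(key=lambda c: c.p_perm)
    return ClusterResult(clusters, n_permutations, cluster_alpha, seed,
                         threshold)


def achieved_power(n: int, dz: float, alpha: float = 0.05,
                   tail: str = "two") -> float:
    """Power of the one-sample/paired t-test at sample size n."""
    if n < 2:
        return 0.0
    df = n - 1
    ncp = dz * np.sqrt(n)
    if tail == "two":
        tc = sps.t.ppf(1.0 - alpha / 2.0, df)
        return float(sps.nct.sf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp))
    tc = sps.t.ppf(1.0 - alpha, df)
    if tail == "greater":
        return float(sps.nct.sf(tc, df, ncp))
    return float(sps.nct.cdf(-tc, df, -abs(ncp)))


def power_sample_size(dz: float, alpha: float = 0.05, power: float = 0.80,
                      tail: str = "two", n_max: int = 1_000_000
                      ) -> PowerResult:
    """Smallest n whose t-test power reaches the target, via noncentral t."""
    if dz == 0:
        raise StatsError("dz must be nonzero")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise StatsError("alpha and power must lie in (0, 1)")
    dz = abs(dz)
    for n in range(2, n_max + 1):
        p = achieved_power(n, dz, alpha, tail)
        if p >= power:
            return PowerResult(n, dz, alpha, power, p)
    raise StatsError(f"target power unreachable within n <= {n_max}")


# ---------------------------------------------------------------------------
# Report assembly

@dataclass
class StatReport:
    comparisons: dict[str, dict] = field(default_factory=dict)
    clusters: list[dict] = field(default_factory=list)
    power: dict | None = None
    seeds: dict[str, int] = field(default_factory=dict)

    def add_ttest(self, name: str, t_res: TTestResult,
                  bf: BayesFactorResult | None = None) -> None:
        entry = asdict(t_res)
        if bf is not None:
            entry["bf10"] = bf.bf10
            entry["bf01"] = bf.bf01
            entry["prior_r"] = bf.r
        self.comparisons[name] = entry

    def add_clusters(self, result: ClusterResult) -> None:
        self.clusters = [asdict(c) for c in result.clusters]
        self.seeds["cluster_permutation"] = result.seed

    def to_json(self, path=None) -> str:
        payload = {
            "comparisons": self.comparisons,
            "clusters": self.clusters,
            "power": self.power,
            "seeds": self.seeds,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = []
        for name, c in self.comparisons.items():
            line = (f"{name}: t({c['df']}) = {c['t']:.2f}, p = {c['p']:.3f}, "
                    f"dz = {c['dz']:.2f}")
            if "bf10" in c:
                line += f", BF10 = {c['bf10']:.2f}"
            lines.append(line)
        for cl in self.clusters:
            lines.append(f"cluster {cl['start_ms']:.0f}-{cl['end_ms']:.0f} ms: "
                         f"t_sum = {cl['t_sum']:.2f}, p = {cl['p_perm']:.4f}")
        if self.power:
            lines.append(f"required n = {self.power['n_required']} "
                         f"(dz = {self.power['dz']}, "
                         f"power = {self.power['power']})")
        return "\n".join(lines)
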