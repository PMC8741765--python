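"""Synthetic tongue-feature cohort generator.

The study cohort (2,675 participants, 1,658 of them with diabetes
mellitus) is private; this module generates stand-in cohorts whose
per-feature marginal counts reproduce the published cohort composition
exactly (quota mode) or in expectation (multinomial mode), and whose
labels follow a logistic class-conditional model.

Label model.  Each record receives a linear score ``s = sum of
per-category log-odds offsets`` over its active categories; the DM
probability is ``sigmoid(b + s)`` with the intercept ``b`` calibrated by
bisection so the expected DM count equals ``n_dm``.  The default offsets
put +1 log-odds on thick fur, yellow fur, bluish tongue and teeth
markings — the tongue signs conventionally associated with high diabetes
prevalence — and 0 elsewhere.  Features are sampled independently given
the marginals except for one tie: every record with no fur coating
(``fur_thickness == no_fur``) has ``fur_color == none``.

Published fur-colour counts sum to 2,400 of 2,675; the remaining 275
records are assigned the explicit ``none`` colour (217 of which are the
``no_fur`` records).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from . import schema
from .errors import CalibrationError, ConfigError, DataError
from .schema import DM, NON_DM, TongueRecord

#: published cohort composition: per-feature category counts (n = 2675)
TABLE1_COUNTS: dict[str, dict[str, int]] = {
    "tongue_body": {"medium": 1332, "enlarged": 915, "small": 428},
    "tongue_color": {"mild_red": 1400, "red": 677, "pale": 375, "bluish": 223},
    "teeth_markings": {"yes": 1662, "no": 1013},
    "fur_color": {"white": 1203, "black": 201, "yellow": 996, "none": 275},
    "saliva": {"normal": 1884, "dry": 518, "wet": 273},
    "fur_thickness": {"thin": 852, "thick": 1606, "no_fur": 217},
}

#: multi-label surface-mark prevalences (counts out of 2675)
SURFACE_COUNTS: dict[str, int] = {
    "red_spots": 1489,
    "black_spots": 1044,
    "fissures": 1038,
    "petechiae": 205,
}

N_TOTAL_DEFAULT = 2675
N_DM_DEFAULT = 1658

#: seasonal acquisition phases: (name, DM count, non-DM count)
PHASES: tuple[tuple[str, int, int], ...] = (
    ("dec_jan", 272, 258),
    ("mar_may", 483, 267),
    ("jun_sep", 723, 339),
    ("oct", 180, 153),
)


def default_effects() -> dict[str, dict[str, float]]:
    """Default class-conditional log-odds offsets (+1 on the four
    DM-associated signs, 0 elsewhere)."""
    return {
        "fur_thickness": {"thick": 1.0},
        "fur_color": {"yellow": 1.0},
        "tongue_color": {"bluish": 1.0},
        "teeth_markings": {"yes": 1.0},
    }


def strong_effects(scale: float = 2.0) -> dict[str, dict[str, float]]:
    """Strong +/-``scale`` log-odds effect model: +scale on the four
    DM-associated categories, -scale on every other category of those
    four features.  With scale=2 the Bayes accuracy of the induced task
    is about 0.90."""
    eff: dict[str, dict[str, float]] = {
        "fur_thickness": {}, "fur_color": {}, "tongue_color": {}, "teeth_markings": {}
    }
    risk = {
        "fur_thickness": "thick",
        "fur_color": "yellow",
        "tongue_color": "bluish",
        "teeth_markings": "yes",
    }
    for feat, cats in TABLE1_COUNTS.items():
        if feat not in eff:
            continue
        for cat in cats:
            eff[feat][cat] = scale if cat == risk[feat] else -scale
    return eff


def null_effects() -> dict[str, dict[str, float]]:
    """All offsets zero: labels independent of features."""
    return {}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one synthetic cohort.

    ``marginals`` maps feature -> category -> count (quota mode) or
    probability (multinomial mode); surface marks are listed under their
    own flag names.  ``effects`` maps feature -> category -> log-odds
    offset toward DM.
    """

    n_total: int = N_TOTAL_DEFAULT
    n_dm: int = N_DM_DEFAULT
    marginals: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {**TABLE1_COUNTS, "surface": SURFACE_COUNTS}
    )
    effects: Mapping[str, Mapping[str, float]] = field(default_factory=default_effects)
    sampling_mode: str = "quota"
    include_phase: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_mode not in ("quota", "multinomial"):
            raise ConfigError(f"unknown sampling_mode: {self.sampling_mode!r}")
        if not (0 <= self.n_dm <= self.n_total):
            raise ConfigError("require 0 <= n_dm <= n_total")
        for feat in list(schema.CATEGORICAL_FEATURES) + ["teeth_markings"]:
            if feat not in self.marginals:
                raise ConfigError(f"missing marginal for feature {feat!r}")
        self._check_marginals()

    def _check_marginals(self) -> None:
        for feat, cats in self.marginals.items():
            if feat == "surface":
                continue
            vals = list(cats.values())
            if self.sampling_mode == "quota":
                if any(v != int(v) for v in vals):
                    raise ConfigError(
                        f"quota mode requires integer counts; {feat} has {vals}"
                    )
                if sum(int(v) for v in vals) != self.n_total:
                    raise ConfigError(
                        f"{feat} counts sum to {sum(vals)}, expected {self.n_total}"
                    )
            else:
                total = sum(vals)
                # counts are accepted in multinomial mode and normalised
                if not math.isclose(total, 1.0, abs_tol=1e-9) and not math.isclose(
                    total, self.n_total, rel_tol=1e-9
                ):
                    raise ConfigError(
                        f"{feat} marginal must sum to 1 or n_total, got {total}"
                    )

    def probabilities(self, feat: str) -> dict[str, float]:
        cats = self.marginals[feat]
        total = sum(cats.values())
        return {c: v / total for c, v in cats.items()}


def scaled_spec(n_total: int, n_dm: int, seed: int = 0, **kw) -> CohortSpec:
    """A spec with the published marginal proportions rescaled to
    ``n_total`` (largest-remainder rounding keeps quota counts exact)."""
    marg: dict[str, dict[str, float]] = {}
    for feat, cats in TABLE1_COUNTS.items():
        counts = _largest_remainder(
            [v / N_TOTAL_DEFAULT for v in cats.values()], n_total
        )
        marg[feat] = dict(zip(cats.keys(), counts))
    marg["surface"] = {
        k: int(round(v / N_TOTAL_DEFAULT * n_total)) for k, v in SURFACE_COUNTS.items()
    }
    return CohortSpec(n_total=n_total, n_dm=n_dm, marginals=marg, seed=seed, **kw)


def _largest_remainder(probs: Sequence[float], n: int) -> list[int]:
    raw = [p * n for p in probs]
    base = [int(math.floor(x)) for x in raw]
    short = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)])  # largest remainder first
    for i in order[:short]:
        base[i] += 1
    return base


def _quota_column(rng: np.random.Generator, counts: Mapping[str, int], n: int) -> np.ndarray:
    col = np.repeat(
        np.array(list(counts.keys()), dtype=object),
        np.array([int(v) for v in counts.values()]),
    )
    if len(col) != n:
        raise ConfigError(f"quota counts sum to {len(col)}, expected {n}")
    rng.shuffle(col)
    return col


def _multinomial_column(
    rng: np.random.Generator, probs: Mapping[str, float], n: int
) -> np.ndarray:
    cats = list(probs.keys())
    p = np.array(list(probs.values()))
    return rng.choice(np.array(cats, dtype=object), size=n, p=p / p.sum())


def calibrate_intercept(scores: np.ndarray, target_rate: float, tol: float = 1e-12) -> float:
    """Bisect for the intercept b with mean(sigmoid(b + s)) == target_rate.

    The mean is strictly increasing in b, so bisection converges whenever
    0 < target_rate < 1; anything else raises :class:`CalibrationError`.
    """
    if not (0.0 < target_rate < 1.0):
        raise CalibrationError(f"target DM rate {target_rate} not in (0, 1)")
    lo, hi = -50.0, 50.0
    f = lambda b: float(np.mean(expit(b + scores))) - target_rate
    if f(lo) > 0 or f(hi) < 0:
        raise CalibrationError("offsets too extreme: intercept bracket failed")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    else:
        raise CalibrationError("intercept bisection did not converge")
    return 0.5 * (lo + hi)


def _effect_scores(columns: dict[str, np.ndarray], effects, n: int) -> np.ndarray:
    s = np.zeros(n)
    for feat, cats in effects.items():
        for cat, off in cats.items():
            if feat in columns:
                s += np.where(columns[feat] == cat, float(off), 0.0)
            elif feat == "surface":  # offsets on individual surface flags
                raise ConfigError("surface effects must name the flag column")
            else:
                s += np.where(columns[feat] == cat, float(off), 0.0)
    return s


def dm_probabilities(spec: CohortSpec, columns: dict[str, np.ndarray]) -> np.ndarray:
    """Calibrated per-record P(DM | features) under the spec's effect model."""
    s = _effect_scores(columns, spec.effects, spec.n_total)
    b = calibrate_intercept(s, spec.n_dm / spec.n_total)
    return expit(b + s)


def simulate_cohort(spec: CohortSpec) -> list[TongueRecord]:
    """Draw one cohort; identical spec (including seed) gives an
    identical cohort.

    Quota mode: every single-valued feature's category counts equal the
    spec counts exactly and exactly ``n_dm`` records are DM (weighted
    sampling without replacement, weights = logistic probabilities).
    Multinomial mode: marginals and DM count hold in expectation, labels
    are independent Bernoulli(p_i).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_total
    quota = spec.sampling_mode == "quota"

    cols: dict[str, np.ndarray] = {}
    for feat in ("tongue_body", "tongue_color", "saliva", "teeth_markings"):
        if quota:
            cols[feat] = _quota_column(rng, spec.marginals[feat], n)
        else:
            cols[feat] = _multinomial_column(rng, spec.probabilities(feat), n)

    # fur thickness first, then colour with the no_fur -> none tie
    if quota:
        cols["fur_thickness"] = _quota_column(rng, spec.marginals["fur_thickness"], n)
        color_counts = {k: int(v) for k, v in spec.marginals["fur_color"].items()}
        no_fur_idx = np.flatnonzero(cols["fur_thickness"] == "no_fur")
        n_none = color_counts.get("none", 0)
        if n_none < len(no_fur_idx):
            raise ConfigError(
                "fur_color 'none' count smaller than fur_thickness 'no_fur' count"
            )
        color = np.empty(n, dtype=object)
        color[no_fur_idx] = "none"
        rest_counts = dict(color_counts)
        rest_counts["none"] = n_none - len(no_fur_idx)
        rest_idx = np.flatnonzero(cols["fur_thickness"] != "no_fur")
        rest = _quota_column(rng, rest_counts, len(rest_idx))
        color[rest_idx] = rest
        cols["fur_color"] = color
    else:
        cols["fur_thickness"] = _multinomial_column(
            rng, spec.probabilities("fur_thickness"), n
        )
        pc = spec.probabilities("fur_color")
        p_nofur = spec.probabilities("fur_thickness").get("no_fur", 0.0)
        # conditional colour distribution for records with fur present
        resid_none = max(pc.get("none", 0.0) - p_nofur, 0.0)
        cond = {c: (resid_none if c == "none" else p) for c, p in pc.items()}
        color = _multinomial_column(rng, cond, n)
        color[cols["fur_thickness"] == "no_fur"] = "none"
        cols["fur_color"] = color

    surface = spec.marginals.get("surface", SURFACE_COUNTS)
    flags: dict[str, np.ndarray] = {}
    for mark in schema.SURFACE_MARKS:
        c = surface.get(mark, 0)
        if quota:
            count = int(c)
            arr = np.zeros(n, dtype=bool)
            arr[rng.choice(n, size=count, replace=False)] = True
        else:
            p = c if c <= 1 else c / n
            arr = rng.random(n) < p
        flags[mark] = arr

    p_dm = dm_probabilities(spec, cols)
    if quota:
        # conditional Bernoulli: the joint law of independent Bernoulli(p_i)
        # labels conditioned on exactly n_dm successes; since the intercept
        # is calibrated so that E[sum] = n_dm, per-record inclusion
        # probabilities stay close to p_i while the DM count is exact
        dm_mask = _conditional_bernoulli(rng, p_dm, spec.n_dm)
        labels = np.where(dm_mask, DM, NON_DM).astype(object)
    else:
        labels = np.where(rng.random(n) < p_dm, DM, NON_DM).astype(object)

    phases = _assign_phases(rng, labels) if spec.include_phase else [None] * n

    records = []
    for i in range(n):
        records.append(
            TongueRecord(
                tongue_body=cols["tongue_body"][i],
                tongue_color=cols["tongue_color"][i],
                red_spots=bool(flags["red_spots"][i]),
                black_spots=bool(flags["black_spots"][i]),
                fissures=bool(flags["fissures"][i]),
                petechiae=bool(flags["petechiae"][i]),
                teeth_markings=cols["teeth_markings"][i] == "yes",
                fur_color=cols["fur_color"][i],
                saliva=cols["saliva"][i],
                fur_thickness=cols["fur_thickness"][i],
                label=labels[i],
                phase=phases[i],
            )
        )
    return records


def _conditional_bernoulli(rng: np.random.Generator, p: np.ndarray, m: int) -> np.ndarray:
    """Sample z ~ independent Bernoulli(p_i) conditioned on sum(z) = m.

    Backward dynamic program over P(count of successes among items i..n),
    with per-item renormalisation (scaling cancels in the sequential
    inclusion ratios), then a forward sequential draw.
    """
    n = len(p)
    if not 0 <= m <= n:
        raise ConfigError(f"cannot draw {m} successes from {n} records")
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    # f[i] = normalised distribution of the success count over items i..n-1
    f = np.zeros((n + 1, m + 2))
    f[n, 0] = 1.0
    for i in range(n - 1, -1, -1):
        f[i, 1:] = p[i] * f[i + 1, :-1]
        f[i, :] += (1.0 - p[i]) * f[i + 1, :]
        tot = f[i].sum()
        if tot > 0:
            f[i] /= tot
    z = np.zeros(n, dtype=bool)
    need = m
    for i in range(n):
        if need == 0:
            break
        denom = p[i] * f[i + 1, need - 1] + (1.0 - p[i]) * f[i + 1, need]
        incl = 1.0 if denom <= 0 else p[i] * f[i + 1, need - 1] / denom
        if rng.random() < incl:
            z[i] = True
            need -= 1
        if need > n - i - 1:  # remaining items must all succeed
            z[i + 1 :] = True
            need = 0
            break
    return z


def _assign_phases(rng: np.random.Generator, labels: np.ndarray) -> list[str]:
    """Assign acquisition phases label-conditionally, proportional to the
    published phase-by-class sizes (no phase effect on features)."""
    n = len(labels)
    phases = np.empty(n, dtype=object)
    for lab, col in ((DM, 1), (NON_DM, 2)):
        idx = np.flatnonzero(labels == lab)
        sizes = [p[col] for p in PHASES]
        tot = sum(sizes)
        counts = _largest_remainder([s / tot for s in sizes], len(idx))
        pool = np.repeat(np.array([p[0] for p in PHASES], dtype=object), counts)
        rng.shuffle(pool)
        phases[idx] = pool
    return list(phases)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_cohort(
    records: Sequence[TongueRecord], train_fraction: float, seed: int = 0
) -> tuple[list[TongueRecord], list[TongueRecord]]:
    """Stratified train/test split.

    Per class, the train size is round-half-up(train_fraction x class
    size); e.g. the published 1658/1017 cohort at 0.7 splits into
    1161 + 712 train and 497 + 305 test.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ConfigError("train_fraction must lie in (0, 1)")
    labels = [r.label for r in records]
    if any(l is None for l in labels):
        raise DataError("all records must be labeled for splitting")
    rng = np.random.default_rng(seed)
    train: list[TongueRecord] = []
    test: list[TongueRecord] = []
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        if len(idx) < 2:
            raise DataError(f"class {lab!r} has fewer than 2 records")
        idx = np.array(idx)
        rng.shuffle(idx)
        k = _round_half_up(train_fraction * len(idx))
        train.extend(records[i] for i in idx[:k])
        test.extend(records[i] for i in idx[k:])
    return train, test
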