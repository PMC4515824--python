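"""From spot densities to immunophenotypes, titration fits and diagnoses.

The central estimator: the percentage of cells positive for a CD equals
the bound-cell density on the matching antibody spot normalised to the
anti-CD45 (positive control) density, times 100.  Because the saturation
law shares its characteristic concentration across spots, the estimate is
invariant to the analysed-suspension concentration.

Also here: the shared-x0 global titration fit, the morphotype x antibody
cross-tabulation with immunophenotype calls, percentile reference
intervals, Mann-Whitney cohort comparison (exact for small samples), the
flow-cytometry concordance summary, and rule-based disease-signature
scoring over reference-interval flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, pearsonr

from .capture import CaptureResult, SaturationParams
from .signatures import DEFAULT_SIGNATURES, DiseaseSignature


@dataclass
class ProfileTable:
    """Per-antibody raw and CD45-normalised densities for one sample."""

    raw: pd.Series  # cells/mm^2
    normalized: pd.Series  # % of anti-CD45 density
    over_100: list[str] = field(default_factory=list)  # flagged, not clipped

    def __post_init__(self) -> None:
        if (self.raw < 0).any():
            raise ValueError("densities must be >= 0")


def normalize(densities: pd.Series | dict, reference: str = "CD45") -> ProfileTable:
    """Normalise per-spot densities to the positive-control spot (x100)."""
    raw = pd.Series(densities, dtype=float)
    if reference not in raw.index:
        raise ValueError(f"no {reference} spot in the density table")
    ref = raw[reference]
    if ref <= 0:
        raise ValueError("normalization undefined: CD45 density is zero")
    normd = 100.0 * raw / ref
    over = [str(i) for i in normd.index[(normd > 100.0) & (normd.index != reference)]]
    return ProfileTable(raw, normd, over)


def counting_noise(
    density: float | np.ndarray,
    rng: np.random.Generator,
    n_fields: int = 3,
    field_sd: float = 0.05,
):
    """Replicate-field counting noise: mean of ``n_fields`` multiplicative
    draws with 5% SD each, emulating the 3-picture counting protocol."""
    d = np.asarray(density, dtype=float)
    factors = 1.0 + field_sd * rng.standard_normal((n_fields,) + d.shape)
    return np.maximum(d * factors.mean(axis=0), 0.0)


def profile_from_capture(
    capture: CaptureResult,
    seed: int | None = None,
    n_fields: int = 3,
    field_sd: float = 0.05,
) -> ProfileTable:
    """Profile a simulated array, with optional replicate-field counting noise."""
    dens = capture.density_table()
    if seed is not None:
        rng = np.random.default_rng(seed)
        dens = pd.Series(
            counting_noise(dens.to_numpy(), rng, n_fields, field_sd), index=dens.index
        )
    dens = dens.drop(labels=["mIgG"], errors="ignore")
    return normalize(dens)


# ---------------------------------------------------------------------------
# titration fit


def fit_saturation(
    titration: pd.DataFrame,
) -> tuple[SaturationParams, dict[str, float]]:
    """Global fit of y_i = a_i * (1 - exp(-x/x0)) with a shared x0.

    ``titration`` needs columns ``x`` (1e6 cells/ml), ``spot`` and
    ``density``.  Returns the fitted parameters and their standard errors
    (keys ``x0`` and ``a:<spot>``) from the Gauss-Newton covariance.
    """
    x = titration["x"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need >= 3 distinct suspension concentrations")
    spots = list(dict.fromkeys(titration["spot"]))
    y = titration["density"].to_numpy(dtype=float)
    spot_idx = np.array([spots.index(s) for s in titration["spot"]])

    rel_span = [
        (np.ptp(y[spot_idx == i]) / max(np.abs(y[spot_idx == i]).max(), 1e-12))
        for i in range(len(spots))
    ]
    if all(r < 1e-9 for r in rel_span):
        raise ValueError("x0 unidentifiable: every titration series is flat in x")

    def model(p):
        x0 = p[0]
        a = p[1:]
        return a[spot_idx] * (1.0 - np.exp(-x / x0))

    p0 = np.concatenate([[np.median(x) / 2.0], [y[spot_idx == i].max() for i in range(len(spots))]])
    res = optimize.least_squares(lambda p: model(p) - y, p0, bounds=(1e-9, np.inf))
    dof = max(len(y) - len(res.x), 1)
    s2 = 2.0 * res.cost / dof
    J = res.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(len(res.x), np.nan)
    params = SaturationParams(x0=float(res.x[0]), a=dict(zip(spots, map(float, res.x[1:]))))
    errors = {"x0": float(se[0]), **{f"a:{s}": float(e) for s, e in zip(spots, se[1:])}}
    return params, errors


# ---------------------------------------------------------------------------
# cross-tabulation and immunophenotype calls


@dataclass
class MorphotypeByAntibody:
    mean_percent: pd.DataFrame  # antibody x morphotype
    sem_percent: pd.DataFrame
    n_donors: int
    flagged: list[str] = field(default_factory=list)  # antibodies with no cells


def crosstab(per_donor: list[pd.DataFrame], min_cells: int = 200) -> MorphotypeByAntibody:
    """Average morphotype composition per antibody across donors.

    Each element of ``per_donor`` is one donor's classified capture: one
    row per cell with columns ``antibody`` and ``morphotype``.  Rows are
    percentages (sum 100) averaged with the s.e.m. across donors.
    """
    if not per_donor:
        raise ValueError("need at least one donor")
    tables = []
    for i, df in enumerate(per_donor):
        counts = pd.crosstab(df["antibody"], df["morphotype"])
        totals = counts.sum(axis=1)
        low = totals[totals < min_cells]
        for ab, n in low.items():
            warnings.warn(f"donor {i}: only {n} classified cells for {ab}", stacklevel=2)
        tables.append(100.0 * counts.div(totals, axis=0))
    stacked = pd.concat(tables, keys=range(len(tables)))
    mean = stacked.groupby(level=1).mean().fillna(0.0)
    sem = stacked.groupby(level=1).sem(ddof=1).fillna(0.0) if len(tables) > 1 else mean * 0.0
    all_abs = set().union(*(set(t.index) for t in tables))
    flagged = sorted(a for a in all_abs if a not in mean.index)
    return MorphotypeByAntibody(mean, sem, len(per_donor), flagged)


@dataclass
class ImmunophenotypeCall:
    morphotype: str
    calls: dict[str, str]  # CD -> positive | negative | indeterminate
    fractions: dict[str, float]  # supporting mean %


def call_immunophenotype(
    xtab: MorphotypeByAntibody,
    morphotype: str,
    nonspecific_bound: float = 2.0,
) -> ImmunophenotypeCall:
    """Infer a morphotype's immunophenotype from which antibodies capture it.

    Per CD: negative when the morphotype's share of that spot's cells is
    at or below the nonspecific bound; positive when the share minus two
    s.e.m. clears the bound; indeterminate otherwise.
    """
    if morphotype not in xtab.mean_percent.columns:
        raise ValueError(f"morphotype {morphotype!r} absent from the cross-tab")
    calls, fracs = {}, {}
    for ab in xtab.mean_percent.index:
        m = float(xtab.mean_percent.loc[ab, morphotype])
        s = float(xtab.sem_percent.loc[ab, morphotype])
        fracs[ab] = m
        if m <= nonspecific_bound:
            calls[ab] = "negative"
        elif m - 2.0 * s > nonspecific_bound:
            calls[ab] = "positive"
        else:
            calls[ab] = "indeterminate"
    return ImmunophenotypeCall(morphotype, calls, fracs)


# ---------------------------------------------------------------------------
# Mann-Whitney U


@dataclass
class TestResult:
    U: float
    p: float
    n1: int
    n2: int


_EXACT_LIMIT = 12


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a with midrank ties."""
    pooled = np.concatenate([a, b])
    order = pooled.argsort(kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def mann_whitney(sample_a, sample_b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact permutation null (ties included) when n1 + n2 <= 12, otherwise
    the normal approximation with tie-corrected variance and continuity
    correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= _EXACT_LIMIT:
        pooled = np.concatenate([a, b])
        dev = abs(u - mu)
        hits = total = 0
        for pick in combinations(range(n1 + n2), n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(pick)] = True
            uu = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(uu - mu) >= dev - 1e-12:
                hits += 1
        return TestResult(u, hits / total, n1, n2)

    pooled = np.concatenate([a, b])
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum() / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, n1, n2)
    z = (abs(u - mu) - 0.5) / np.sqrt(var)
    p = float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))
    return TestResult(u, p, n1, n2)


# ---------------------------------------------------------------------------
# reference intervals and diagnosis


def reference_ranges(cohort_profiles: list[ProfileTable]) -> pd.DataFrame:
    """Per-CD median and 2.5-97.5 percentile interval of a healthy cohort."""
    if len(cohort_profiles) < 3:
        raise ValueError("need at least 3 donors for reference ranges")
    if len(cohort_profiles) < 20:
        warnings.warn(
            f"only {len(cohort_profiles)} donors; reference intervals will be unstable",
            stacklevel=2,
        )
    mat = pd.concat([p.normalized for p in cohort_profiles], axis=1)
    return pd.DataFrame(
        {
            "median": mat.median(axis=1),
            "lo": mat.quantile(0.025, axis=1),
            "hi": mat.quantile(0.975, axis=1),
        }
    )


@dataclass
class DiagnosisSuggestion:
    disease: str
    score: float
    matched: list[str]
    mismatched: list[str]
    morphotype_support: bool | None = None


def flag_profile(profile: ProfileTable, ranges: pd.DataFrame) -> pd.Series:
    """Per-CD flag: 'above', 'below' or 'within' the reference interval."""
    missing = [cd for cd in ranges.index if cd not in profile.normalized.index]
    if missing:
        raise ValueError(f"panel mismatch: profile lacks {missing}")
    out = {}
    for cd in ranges.index:
        v = profile.normalized[cd]
        if v > ranges.loc[cd, "hi"]:
            out[cd] = "above"
        elif v < ranges.loc[cd, "lo"]:
            out[cd] = "below"
        else:
            out[cd] = "within"
    return pd.Series(out)


def suggest_diagnosis(
    profile: ProfileTable,
    ranges: pd.DataFrame,
    signatures: list[DiseaseSignature] | None = None,
    morph_evidence: dict[str, float] | None = None,
) -> list[DiagnosisSuggestion]:
    """Rank disease signatures by the fraction of matched expectations.

    ``morph_evidence`` optionally maps morphotype -> % among captured
    cells to corroborate signatures with a morphotype requirement.
    Returns [('normal', 1.0, ...)] when no CD is flagged.
    """
    signatures = signatures if signatures is not None else DEFAULT_SIGNATURES
    flags = flag_profile(profile, ranges)
    if (flags == "within").all():
        return [DiagnosisSuggestion("normal", 1.0, [], [])]
    # "normal" competes as a candidate scored by the fraction of unflagged
    # CDs, so isolated stray flags on a wide panel do not force a disease call
    out = [
        DiagnosisSuggestion(
            "normal",
            float((flags == "within").mean()),
            sorted(flags.index[flags == "within"]),
            sorted(flags.index[flags != "within"]),
        )
    ]
    for sig in signatures:
        matched, mismatched = [], []
        for cd, exp in sig.expectations.items():
            if exp == "variable" or cd not in flags.index:
                continue
            f = flags[cd]
            ok = (
                (exp == "up" and f == "above")
                or (exp == "down" and f == "below")
                or (exp == "normal" and f == "within")
            )
            (matched if ok else mismatched).append(cd)
        n_app = len(matched) + len(mismatched)
        score = len(matched) / n_app if n_app else 0.0
        support = None
        if sig.morphotype_evidence is not None and morph_evidence is not None:
            support = morph_evidence.get(sig.morphotype_evidence, 0.0) > 1.0
        out.append(DiagnosisSuggestion(sig.disease, score, matched, mismatched, support))
    out.sort(key=lambda d: (-d.score, d.disease))
    return out


# ---------------------------------------------------------------------------
# flow-cytometry concordance


@dataclass
class ConcordanceResult:
    pearson_r: dict[str, float]
    slope: float  # pooled through-origin regression of flow on microarray
    n_pairs: int
    undefined: list[str] = field(default_factory=list)


def fc_concordance(paired: pd.DataFrame, min_donors: int = 3) -> ConcordanceResult:
    """Concordance of microarray vs flow percent-positive estimates.

    ``paired`` needs columns ``cd``, ``microarray_pct``, ``flow_pct`` (one
    row per donor x CD).  Per-CD Pearson R plus the pooled through-origin
    slope k = sum(xy)/sum(x^2) with x = microarray, y = flow.
    """
    rs, undefined = {}, []
    for cd, grp in paired.groupby("cd"):
        if len(grp) < min_donors:
            raise ValueError(f"{cd}: need >= {min_donors} paired donors")
        x = grp["microarray_pct"].to_numpy()
        y = grp["flow_pct"].to_numpy()
        if np.std(x) == 0 or np.std(y) == 0:
            undefined.append(str(cd))
            rs[str(cd)] = float("nan")
        else:
            rs[str(cd)] = float(pearsonr(x, y)[0])
    x = paired["microarray_pct"].to_numpy()
    y = paired["flow_pct"].to_numpy()
    slope = float((x * y).sum() / (x * x).sum())
    return ConcordanceResult(rs, slope, len(paired), undefined)
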