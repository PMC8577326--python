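"""Mixed-effects modelling of AUC tables with the study's contrast codes.

The response is one signed AUC value per subject x condition cell.  Fixed
effects are built from sum-to-zero contrast codes::

    Domain      speech -0.5          nonspeech +0.5
    Spectrum    [a] -0.5             [ɛ(ː)] +0.5
    Dimension   duration -0.5        spectrum +0.5
    Deviant     to-E -0.5            from-E +0.5
    Duration    360 -> +1, 220 -> -0.2, 180 -> -0.6   (median-centred)
    LateralityA left/right -0.25     midline +0.5
    LateralityB left -0.5            right +0.5   (midline 0)
    Anteriority central -0.5         frontal +0.5

Models carry per-subject random intercepts plus random slopes (Spectrum
for the onset model; Spectrum and Duration for the offset model; Dimension,
Deviant and their interaction for the MMR models).  Estimation is REML via
:class:`statsmodels.regression.mixed_linear_model.MixedLM`; the bespoke
content here is the coding, the model structure, the cell-mean predictions
with their x'Vx standard errors, and the two-level confidence-interval
mutual-exclusion rule used to localize interactions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "ContrastScheme",
    "ModelSpec",
    "CellEstimate",
    "AucMixedModel",
    "AucMixedModelResults",
    "onset_model_spec",
    "offset_model_spec",
    "mmr_model_spec",
    "build_design",
    "ci_exclusion",
    "ci_verdict",
    "negative_ci_check",
    "CI_MULTIPLIERS",
]

#: CI multipliers exactly as used in the cell-mean tables.
CI_MULTIPLIERS = {0.95: 1.96, 0.90: 1.645}

DURATION_CODE = {360.0: 1.0, 220.0: -0.2, 180.0: -0.6}
CATEGORY_DURATION = {"focal_a": 220.0, "nonfocal_e": 220.0, "short_e": 180.0, "long_e": 360.0}


@dataclass(frozen=True)
class ContrastScheme:
    """Numeric codes for each factor level (see module docstring)."""

    domain: Mapping[str, float] = field(
        default_factory=lambda: {"speech": -0.5, "speech_analogue": -0.5, "nonspeech": 0.5}
    )
    dimension: Mapping[str, float] = field(
        default_factory=lambda: {"durational": -0.5, "spectral": 0.5}
    )
    deviant: Mapping[str, float] = field(
        default_factory=lambda: {"to_E": -0.5, "from_E": 0.5}
    )
    laterality_a: Mapping[str, float] = field(
        default_factory=lambda: {"left": -0.25, "right": -0.25, "midline": 0.5}
    )
    laterality_b: Mapping[str, float] = field(
        default_factory=lambda: {"left": -0.5, "right": 0.5, "midline": 0.0}
    )
    anteriority: Mapping[str, float] = field(
        default_factory=lambda: {"central": -0.5, "frontal": 0.5}
    )
    duration: Mapping[float, float] = field(default_factory=lambda: dict(DURATION_CODE))

    def spectrum_code(self, category: str) -> float:
        # [a] vs the [ɛ] family (short, intermediate and long variants)
        return -0.5 if category == "focal_a" else 0.5

    def code(self, factor: str, row: Mapping) -> float:
        """Contrast code of ``factor`` for one data row."""
        try:
            if factor == "domain":
                return self.domain[row["domain"]]
            if factor == "spectrum":
                return self.spectrum_code(row["category"])
            if factor == "dimension":
                return self.dimension[row["dimension"]]
            if factor == "deviant":
                return self.deviant[row["deviant"]]
            if factor == "latA":
                return self.laterality_a[_laterality_of(row)]
            if factor == "latB":
                return self.laterality_b[_laterality_of(row)]
            if factor == "ant":
                return self.anteriority[_anteriority_of(row)]
            if factor == "duration":
                dur = row.get("duration_ms") or CATEGORY_DURATION[row["category"]]
                return self.duration[float(dur)]
        except KeyError as exc:
            raise ValueError(f"unknown level {exc} for factor {factor!r}") from None
        raise ValueError(f"unknown factor {factor!r}")


def _laterality_of(row: Mapping) -> str:
    if "region" in row and isinstance(row["region"], str):
        return row["region"]
    ch = row["channel"]
    return {"3": "left", "Z": "midline", "4": "right"}[ch[-1].upper()]


def _anteriority_of(row: Mapping) -> str:
    if "anteriority" in row and isinstance(row["anteriority"], str):
        return row["anteriority"]
    ch = row["channel"]
    return {"F": "frontal", "C": "central"}[ch[0].upper()]


def _with_location_interactions(factors: Sequence[str], locations: Sequence[str]) -> tuple[str, ...]:
    """Main effects, their mutual interactions, and all their crossings
    with each location contrast (the study's model structure)."""
    terms: list[str] = list(factors)
    factor_sets = [
        list(c) for r in range(2, len(factors) + 1) for c in combinations(factors, r)
    ]
    terms += [":".join(c) for c in factor_sets]
    terms += list(locations)
    for loc in locations:
        terms += [f"{f}:{loc}" for f in factors]
        terms += [":".join(c + [loc]) for c in factor_sets]
    return tuple(terms)


def onset_model_spec() -> "ModelSpec":
    """Onset-ERP model: Domain x Spectrum crossed with the location contrasts."""
    return ModelSpec(
        terms=_with_location_interactions(["domain", "spectrum"], ["latA", "latB", "ant"]),
        random_slopes=("spectrum",),
    )


def offset_model_spec() -> "ModelSpec":
    """Offset-ERP model: the onset model plus Duration and its Domain and
    location interactions."""
    extra = (
        "duration", "domain:duration",
        "duration:latA", "duration:latB", "duration:ant",
        "domain:duration:latA", "domain:duration:latB", "domain:duration:ant",
    )
    return ModelSpec(
        terms=onset_model_spec().terms + extra,
        random_slopes=("spectrum", "duration"),
    )


def mmr_model_spec() -> "ModelSpec":
    """MMR model: Domain x Dimension x Deviant crossed with laterality."""
    return ModelSpec(
        terms=_with_location_interactions(
            ["domain", "dimension", "deviant"], ["latA", "latB"]
        ),
        random_slopes=("dimension", "deviant", "dimension:deviant"),
    )


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-term list (colon-joined interactions) and random slopes."""

    terms: tuple[str, ...]
    random_slopes: tuple[str, ...] = ()
    response: str = "value"
    groups: str = "subject"

    def __post_init__(self) -> None:
        have = set(self.terms)
        # hierarchy check: every interaction's constituents must be present
        for t in self.terms:
            parts = t.split(":")
            if len(parts) > 1:
                missing = [p for p in parts if p not in have]
                if missing:
                    raise ValueError(
                        f"interaction {t!r} lacks main effect(s) {missing}"
                    )


def build_design(
    records: pd.DataFrame,
    spec: ModelSpec,
    scheme: ContrastScheme = ContrastScheme(),
) -> pd.DataFrame:
    """Numeric design table: one coded column per term, interactions as
    products of their constituent codes; includes the intercept."""
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(records))}
    base = sorted({p for t in spec.terms for p in t.split(":")})
    coded = {
        f: records.apply(lambda r, f=f: scheme.code(f, r), axis=1).to_numpy()
        for f in base
    }
    for t in spec.terms:
        parts = t.split(":")
        v = coded[parts[0]].copy()
        for p in parts[1:]:
            v = v * coded[p]
        cols[t] = v
    return pd.DataFrame(cols, index=records.index)


@dataclass(frozen=True)
class CellEstimate:
    """Model-predicted cell mean and its standard error (µV·ms)."""

    mean: float
    se: float
    coords: tuple = ()

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("standard error must be positive")

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        m = CI_MULTIPLIERS[level]
        return (self.mean - m * self.se, self.mean + m * self.se)


def ci_exclusion(a: CellEstimate, b: CellEstimate, level: float = 0.95) -> bool:
    """Mutual confidence-interval exclusion of two cell means.

    True iff each mean lies outside the other's ``level`` CI
    (mean ± 1.96·SE at 95%, mean ± 1.645·SE at 90%).  Symmetric in its
    arguments; shrinking either SE can only keep or create exclusivity.
    """
    lo_a, hi_a = a.ci(level)
    lo_b, hi_b = b.ci(level)
    a_outside_b = a.mean < lo_b or a.mean > hi_b
    b_outside_a = b.mean < lo_a or b.mean > hi_a
    return a_outside_b and b_outside_a


def ci_verdict(a: CellEstimate, b: CellEstimate) -> str:
    """'exclusive_95' (**), 'exclusive_90' (*), or 'not_exclusive'."""
    if ci_exclusion(a, b, 0.95):
        return "exclusive_95"
    if ci_exclusion(a, b, 0.90):
        return "exclusive_90"
    return "not_exclusive"


MARKS = {"exclusive_95": "**", "exclusive_90": "*", "not_exclusive": ""}


def negative_ci_check(e: CellEstimate, level: float = 0.95) -> bool:
    """True iff the entire CI lies below zero (a reliably negative MMR,
    i.e. a mismatch negativity)."""
    return e.mean + CI_MULTIPLIERS[level] * e.se < 0


class AucMixedModel:
    """Linear mixed model for a subject x cell AUC table.

    Parameters
    ----------
    data
        One row per subject x condition cell with the factor columns the
        model terms need (``subject``, ``value``, and e.g. ``domain``,
        ``category``, ``deviant``, ``dimension``, ``region`` or
        ``channel``).
    spec
        Fixed-term list and random slopes; see :func:`onset_model_spec`,
        :func:`offset_model_spec`, :func:`mmr_model_spec`.
    scheme
        Contrast codes (study defaults).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        spec: ModelSpec,
        scheme: ContrastScheme = ContrastScheme(),
    ) -> None:
        if data[spec.groups].nunique() < 2:
            raise ValueError("mixed model needs at least 2 subjects")
        self.data = data.reset_index(drop=True)
        self.spec = spec
        self.scheme = scheme
        self.design = build_design(self.data, spec, scheme)
        self._check_rank()

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, spec: ModelSpec, scheme: ContrastScheme = ContrastScheme()
    ) -> "AucMixedModel":
        return cls(data, spec, scheme)

    def _check_rank(self) -> None:
        X = self.design.to_numpy()
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            # name aliased columns by greedy QR-style elimination
            aliased = []
            keep: list[int] = []
            for j in range(X.shape[1]):
                trial = keep + [j]
                if np.linalg.matrix_rank(X[:, trial]) == len(trial):
                    keep.append(j)
                else:
                    aliased.append(self.design.columns[j])
            raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    def _exog_re(self) -> pd.DataFrame:
        cols = {"Intercept": np.ones(len(self.data))}
        for s in self.spec.random_slopes:
            cols[s] = self.design[s].to_numpy()
        return pd.DataFrame(cols, index=self.design.index)

    def fit(self, reml: bool = True, maxiter: int = 200) -> "AucMixedModelResults":
        """REML fit; a singular random-effects covariance is flagged on the
        results, not fatal."""
        md = MixedLM(
            endog=self.data[self.spec.response].to_numpy(),
            exog=self.design,
            groups=self.data[self.spec.groups].to_numpy(),
            exog_re=self._exog_re(),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = md.fit(reml=reml, maxiter=maxiter)
        return AucMixedModelResults(self, res)


class AucMixedModelResults:
    """Fixed-effect estimates, their covariance, and cell-mean machinery."""

    def __init__(self, model: AucMixedModel, result) -> None:
        self.model = model
        self._res = result
        k = len(model.design.columns)
        self.params = result.fe_params
        self.cov_fe = pd.DataFrame(
            np.asarray(result.cov_params())[:k, :k],
            index=model.design.columns,
            columns=model.design.columns,
        )
        # diagonal can dip microscopically negative on boundary (singular) fits
        self.bse = pd.Series(
            np.sqrt(np.clip(np.diag(self.cov_fe.to_numpy()), 0.0, None)),
            index=model.design.columns,
        )
        self.converged = bool(getattr(result, "converged", True))

    @property
    def singular(self) -> bool:
        """True when the random-effects covariance hit the boundary."""
        try:
            cov_re = np.asarray(self._res.cov_re)
            return bool(np.linalg.eigvalsh(cov_re).min() < 1e-8 * max(1.0, cov_re.max()))
        except Exception:
            return True

    def coef_table(self) -> pd.DataFrame:
        """Estimate / SE / z / p for each fixed term."""
        z = self.params / self.bse
        from scipy.stats import norm

        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "z": z,
                "p": 2 * norm.sf(np.abs(z)),
            }
        )

    def _code_vector(self, cell: Mapping) -> np.ndarray:
        scheme = self.model.scheme
        x = np.empty(len(self.model.design.columns))
        for i, term in enumerate(self.model.design.columns):
            if term == "Intercept":
                x[i] = 1.0
                continue
            v = 1.0
            for p in term.split(":"):
                v *= scheme.code(p, cell)
            x[i] = v
        return x

    def cell_mean(self, **cell) -> CellEstimate:
        """Fixed-effect prediction at one cell (random effects at zero).

        ``cell`` supplies factor levels, e.g. ``domain='speech',
        dimension='durational', deviant='to_E', region='left'``.  SE is
        sqrt(x' V x) with V the fixed-effect covariance.  Raises if a
        needed factor level is missing or unknown (no extrapolation).
        """
        x = self._code_vector(cell)
        mean = float(x @ self.params.to_numpy())
        q = float(x @ self.cov_fe.to_numpy() @ x)
        se = float(np.sqrt(max(q, 0.0)))
        if not se > 0:
            raise ValueError(f"non-positive cell SE (singular fit) for {cell}")
        return CellEstimate(mean=mean, se=se, coords=tuple(sorted(cell.items())))

    def cell_means(self, cells: Iterable[Mapping]) -> pd.DataFrame:
        rows = []
        for cell in cells:
            est = self.cell_mean(**cell)
            rows.append({**cell, "mean": est.mean, "se": est.se})
        return pd.DataFrame(rows)

    def compare_deviants(
        self,
        domains: Sequence[str] = ("speech", "nonspeech"),
        dimensions: Sequence[str] = ("durational", "spectral"),
        regions: Sequence[str] = ("left", "midline", "right"),
    ) -> pd.DataFrame:
        """Cell-mean table with the pairwise to-E vs from-E CI marks.

        One row per deviant cell; the ``mark`` column carries '**' when the
        two deviant means of that (domain, dimension, region) cell are
        mutually exclusive at 95%, '*' at 90% only, '' otherwise.
        """
        cat = {
            ("durational", "to_E"): "short_e",
            ("durational", "from_E"): "long_e",
            ("spectral", "to_E"): "nonfocal_e",
            ("spectral", "from_E"): "focal_a",
        }
        rows = []
        for dom in domains:
            for dim in dimensions:
                for reg in regions:
                    ests = {}
                    for dev in ("to_E", "from_E"):
                        ests[dev] = self.cell_mean(
                            domain=dom, dimension=dim, deviant=dev,
                            region=reg, category=cat[(dim, dev)],
                        )
                    verdict = ci_verdict(ests["to_E"], ests["from_E"])
                    for dev, est in ests.items():
                        rows.append(
                            {
                                "domain": dom, "dimension": dim, "region": reg,
                                "deviant": dev, "mean": est.mean, "se": est.se,
                                "mark": MARKS[verdict],
                                "negative_95": negative_ci_check(est),
                            }
                        )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable fit summary (coefficients + fit diagnostics)."""
        head = (
            f"AucMixedModel ({'REML' if self._res.reml else 'ML'}), "
            f"{self.model.data[self.model.spec.groups].nunique()} subjects, "
            f"{len(self.model.data)} rows; converged={self.converged}, "
            f"singular={self.singular}\n"
        )
        return head + self.coef_table().to_string(float_format=lambda v: f"{v: .3f}")
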