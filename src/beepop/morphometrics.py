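"""Landmark-based wing geometric morphometrics.

TPS file I/O, centroid size, Bookstein baseline registration,
Generalized Procrustes Analysis (GPA) with a GLS consensus, shape PCA,
one-way ANOVA with Fisher's LSD post-hoc comparisons, and forward
stepwise regression of size on geographic covariates.

Size and shape are analysed separately: centroid size (CS) carries the
size signal, while GPA removes translation, scale and rotation so that
the aligned coordinates carry only shape.  Landmark indices are 1-based
in files and public registration arguments (matching how wing landmarks
are numbered on figures) and 0-based internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "LandmarkConfiguration",
    "LandmarkSet",
    "ProcrustesResult",
    "read_tps",
    "write_tps",
    "centroid_size",
    "baseline_register",
    "gpa_align",
    "procrustes_distance",
    "shape_pca",
    "ShapePCAResult",
    "anova_lsd",
    "AnovaResult",
    "stepwise_cs_regression",
    "StepwiseResult",
]

WING_LANDMARKS = {"forewing": 20, "hindwing": 10}
"""Canonical landmark counts for honey-bee wing schemes."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D landmarks (image units)."""

    specimen_id: str
    coords: np.ndarray
    wing: str | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("coords must be a (k, 2) array")
        if self.wing is not None and self.wing in WING_LANDMARKS:
            k = WING_LANDMARKS[self.wing]
            if len(self.coords) != k:
                raise ValueError(
                    f"{self.specimen_id}: {self.wing} requires {k} landmarks, "
                    f"got {len(self.coords)}"
                )

    @property
    def n_landmarks(self) -> int:
        return len(self.coords)


@dataclass
class LandmarkSet:
    """Specimens x landmarks x 2 with per-specimen metadata.

    ``metadata`` is indexed by specimen id; expected columns when
    present: site, region, latitude, longitude, altitude.
    """

    configurations: list[LandmarkConfiguration]
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ks = {c.n_landmarks for c in self.configurations}
        if len(ks) > 1:
            raise ValueError(f"mixed landmark counts in one set: {sorted(ks)}")
        if self.metadata is not None:
            missing = [
                c.specimen_id
                for c in self.configurations
                if c.specimen_id not in self.metadata.index
            ]
            if missing:
                raise ValueError(f"metadata missing for specimens: {missing}")

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        return np.stack([c.coords for c in self.configurations])


# ---------------------------------------------------------------------------
# TPS I/O
# ---------------------------------------------------------------------------

def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Parse a TPS landmark file (LM= / coordinates / IMAGE= / ID= / SCALE=).

    SCALE is applied multiplicatively when present; the specimen id is
    taken from ID=, else IMAGE=, else a running index.
    """
    configs: list[LandmarkConfiguration] = []
    cur_lm: int | None = None
    cur_pts: list[list[float]] = []
    cur_meta: dict[str, str] = {}

    def flush() -> None:
        nonlocal cur_lm, cur_pts, cur_meta
        if cur_lm is None:
            return
        name = cur_meta.get("ID") or cur_meta.get("IMAGE") or str(len(configs))
        if len(cur_pts) != cur_lm:
            raise ValueError(
                f"{path}: specimen {name!r} declares LM={cur_lm} but has "
                f"{len(cur_pts)} coordinate lines"
            )
        coords = np.asarray(cur_pts, dtype=float)
        scale = float(cur_meta["SCALE"]) if "SCALE" in cur_meta else None
        if scale is not None:
            coords = coords * scale
        configs.append(
            LandmarkConfiguration(specimen_id=name, coords=coords, scale=scale)
        )
        cur_lm, cur_pts, cur_meta = None, [], {}

    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key_up = key.strip().upper()
            if key_up == "LM":
                flush()
                cur_lm = int(value)
            elif key_up in ("IMAGE", "ID", "SCALE") and _ == "=":
                cur_meta[key_up] = value.strip()
            else:
                parts = line.split()
                if cur_lm is None or len(parts) != 2:
                    raise ValueError(f"{path}:{ln}: unexpected TPS line: {line!r}")
                cur_pts.append([float(parts[0]), float(parts[1])])
    flush()
    return configs


def write_tps(
    configs: Sequence[LandmarkConfiguration] | LandmarkSet, path: str | Path
) -> None:
    """Write configurations as TPS (raw coordinates; SCALE not re-applied)."""
    if isinstance(configs, LandmarkSet):
        configs = configs.configurations
    with open(path, "w") as fh:
        for c in configs:
            fh.write(f"LM={c.n_landmarks}\n")
            for x, y in c.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={c.specimen_id}\n")


def read_specimen_metadata(path: str | Path) -> pd.DataFrame:
    """Tab-separated specimen metadata table indexed by specimen id."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])


# ---------------------------------------------------------------------------
# Size and registration
# ---------------------------------------------------------------------------

def centroid_size(coords: np.ndarray) -> float:
    """CS = sqrt(sum of squared landmark distances from the centroid)."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def baseline_register(
    coords: np.ndarray, p: int, q: int, one_based: bool = True
) -> np.ndarray:
    """Bookstein baseline registration: landmark p -> (0,0), q -> (1,0).

    A similarity transform (translation, rotation, scale; no
    reflection).  ``p`` and ``q`` are 1-based by default, matching
    landmark numbering in wing figures.
    """
    coords = np.asarray(coords, dtype=float)
    if one_based:
        p, q = p - 1, q - 1
    if p == q:
        raise ValueError("baseline landmarks must differ")
    v = coords[q] - coords[p]
    norm = float(np.hypot(*v))
    if norm == 0.0:
        raise ValueError("baseline landmarks are coincident")
    cos, sin = v / norm
    rot = np.array([[cos, sin], [-sin, cos]])  # rotates v onto +x axis
    return (coords - coords[p]) @ rot.T / norm


# ---------------------------------------------------------------------------
# Generalized Procrustes Analysis
# ---------------------------------------------------------------------------

@dataclass
class ProcrustesResult:
    """GPA output: aligned shapes, GLS consensus, centroid sizes."""

    aligned: np.ndarray  # (n, k, 2), each unit CS
    mean_shape: np.ndarray  # (k, 2), unit CS, zero centroid
    cs: np.ndarray  # (n,), CS of the raw input configurations
    specimen_ids: list[str]
    iterations: int
    converged: bool
    objective: list[float]  # sum of squared distances to consensus per iteration


def _optimal_rotation(shape: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation (det +1, no reflection) minimizing ||shape @ R - target||."""
    u, _, vt = np.linalg.svd(shape.T @ target)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _center_unit(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    return centered / np.sqrt((centered**2).sum())


def gpa_align(
    data: LandmarkSet | Sequence[LandmarkConfiguration] | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> ProcrustesResult:
    """Generalized Procrustes Analysis with a GLS mean shape.

    Each configuration is centered and scaled to unit centroid size
    (full Procrustes), then iteratively rotated onto the running
    consensus by the closed-form orthogonal-Procrustes rotation
    (rotation only, no reflection).  The consensus is the coordinate-
    wise mean, re-centered and re-scaled to unit CS; iteration stops
    when its root-sum-square change falls below ``tol``.
    """
    if isinstance(data, LandmarkSet):
        ids = data.specimen_ids
        arr = data.coords_array()
    elif isinstance(data, np.ndarray):
        arr = np.asarray(data, dtype=float)
        ids = [str(i) for i in range(len(arr))]
    else:
        ids = [c.specimen_id for c in data]
        arr = np.stack([c.coords for c in data])
    if len(arr) < 2:
        raise ValueError("GPA needs at least 2 configurations")

    cs = np.array([centroid_size(c) for c in arr])
    shapes = np.stack([_center_unit(c) for c in arr])

    consensus = _center_unit(shapes[0].copy())
    objective: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(len(shapes)):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = _center_unit(shapes.mean(axis=0))
        # fix the consensus orientation to the previous one so the
        # change criterion measures shape, not a drifting rotation
        new_consensus = new_consensus @ _optimal_rotation(new_consensus, consensus)
        objective.append(float(((shapes - new_consensus) ** 2).sum()))
        change = float(np.sqrt(((new_consensus - consensus) ** 2).sum()))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations", stacklevel=2
        )
    return ProcrustesResult(
        aligned=shapes,
        mean_shape=consensus,
        cs=cs,
        specimen_ids=ids,
        iterations=it,
        converged=converged,
        objective=objective,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Full Procrustes distance between two configurations.

    Both are centered and scaled to unit CS, optimally rotated, and the
    root-sum-square coordinate difference is returned.
    """
    sa, sb = _center_unit(np.asarray(a, float)), _center_unit(np.asarray(b, float))
    sa = sa @ _optimal_rotation(sa, sb)
    return float(np.sqrt(((sa - sb) ** 2).sum()))


def group_mean_shapes(
    result: ProcrustesResult, groups: Mapping[str, str]
) -> dict[str, np.ndarray]:
    """Coordinate-wise mean of aligned members per group label."""
    out: dict[str, np.ndarray] = {}
    labels = [groups[s] for s in result.specimen_ids]
    for label in dict.fromkeys(labels):
        members = [i for i, l in enumerate(labels) if l == label]
        out[label] = result.aligned[members].mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Shape PCA
# ---------------------------------------------------------------------------

@dataclass
class ShapePCAResult:
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    components: np.ndarray
    mean: np.ndarray


def shape_pca(
    aligned: np.ndarray | ProcrustesResult,
    n_components: int | None = None,
    specimen_ids: Sequence[str] | None = None,
) -> ShapePCAResult:
    """PCA of flattened GPA-aligned coordinates (mean-centered)."""
    if isinstance(aligned, ProcrustesResult):
        specimen_ids = aligned.specimen_ids
        aligned = aligned.aligned
    arr = np.asarray(aligned, dtype=float)
    n = len(arr)
    if n < 2:
        raise ValueError("shape PCA needs at least 2 specimens")
    X = arr.reshape(n, -1)
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    evr = S**2 / max((S**2).sum(), 1e-300)
    if n_components is None:
        n_components = min(n - 1, X.shape[1])
    n_components = min(n_components, len(S))
    ids = list(specimen_ids) if specimen_ids is not None else [str(i) for i in range(n)]
    cols = [f"PC{i+1}" for i in range(n_components)]
    return ShapePCAResult(
        scores=pd.DataFrame(U[:, :n_components] * S[:n_components], index=ids, columns=cols),
        explained_variance_ratio=evr[:n_components],
        components=Vt[:n_components],
        mean=mean,
    )


# ---------------------------------------------------------------------------
# ANOVA with Fisher's LSD
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    lsd: pd.DataFrame  # columns: group1, group2, diff, t, p, significant
    letters: dict[str, str]


def anova_lsd(
    values: Sequence[float], groups: Sequence[str], alpha: float = 0.05
) -> AnovaResult:
    """One-way ANOVA with Fisher's LSD pairwise comparisons.

    LSD tests use the pooled within-group mean square with the ANOVA
    within-groups degrees of freedom and, as defined, carry no
    multiplicity correction.  The compact letter display assigns shared
    letters to groups whose means do not differ at ``alpha``.
    """
    y = np.asarray(values, dtype=float)
    labels = list(groups)
    if len(y) != len(labels):
        raise ValueError("values and groups differ in length")
    uniq = list(dict.fromkeys(labels))
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    by = {u: y[[i for i, l in enumerate(labels) if l == u]] for u in uniq}
    for u, arr in by.items():
        if len(arr) < 2:
            raise ValueError(f"group {u!r} has fewer than 2 observations")

    grand = y.mean()
    ssb = sum(len(a) * (a.mean() - grand) ** 2 for a in by.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in by.values())
    dfb = len(uniq) - 1
    dfw = len(y) - len(uniq)
    if ssw == 0.0:
        raise ValueError("zero within-group variance everywhere; F undefined")
    msb = ssb / dfb
    msw = ssw / dfw
    f = msb / msw
    p = float(sps.f.sf(f, dfb, dfw))

    rows = []
    sig: dict[frozenset[str], bool] = {}
    for i, u in enumerate(uniq):
        for v in uniq[i + 1 :]:
            diff = by[u].mean() - by[v].mean()
            se = np.sqrt(msw * (1 / len(by[u]) + 1 / len(by[v])))
            t = diff / se
            pv = float(2 * sps.t.sf(abs(t), dfw))
            s = pv < alpha
            sig[frozenset((u, v))] = s
            rows.append(
                {"group1": u, "group2": v, "diff": diff, "t": t, "p": pv,
                 "significant": s}
            )
    lsd = pd.DataFrame(rows)

    # compact letter display: maximal runs of mutually non-different
    # groups along the means-descending order share a letter
    order = sorted(uniq, key=lambda u: -by[u].mean())
    all_runs: list[tuple[int, int]] = []
    for i in range(len(order)):
        j = i
        while j + 1 < len(order) and all(
            not sig[frozenset((order[m], order[j + 1]))] for m in range(i, j + 1)
        ):
            j += 1
        all_runs.append((i, j))
    # keep maximal runs only (drop any nested in another)
    runs = [
        r
        for r in dict.fromkeys(all_runs)
        if not any(o != r and o[0] <= r[0] <= r[1] <= o[1] for o in all_runs)
    ]
    letters = {u: "" for u in uniq}
    for idx, (i, j) in enumerate(runs):
        ch = chr(ord("a") + idx)
        for m in range(i, j + 1):
            letters[order[m]] += ch
    return AnovaResult(
        f=float(f),
        df_between=dfb,
        df_within=dfw,
        p=p,
        group_means={u: float(a.mean()) for u, a in by.items()},
        lsd=lsd,
        letters=letters,
    )


# ---------------------------------------------------------------------------
# Stepwise regression of size on geography
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    terms: list[str]
    params: pd.Series
    pvalues: pd.Series
    model: object | None  # fitted statsmodels results (None for empty model)
    history: list[str]


def stepwise_cs_regression(
    data: pd.DataFrame,
    response: str = "cs",
    covariates: Sequence[str] = ("latitude", "longitude", "altitude"),
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    adjust_entry: bool = True,
) -> StepwiseResult:
    """Forward stepwise OLS of site-mean centroid size on geography.

    At each step the candidate with the smallest partial-F p-value is
    added if it clears ``alpha_enter``; after each addition any term
    whose p-value exceeds ``alpha_remove`` is dropped.  With
    ``adjust_entry`` (default) the entry threshold is Bonferroni-shared
    across the candidates examined at that step, which keeps the
    family-wise null entry rate near ``alpha_enter``.  Candidates that
    are collinear with the current model never enter.
    """
    import statsmodels.api as sm

    if len(data) < 5:
        raise ValueError("stepwise regression needs at least 5 sites")
    y = data[response].astype(float)
    X_all = data[list(covariates)].astype(float)
    if not np.all(np.isfinite(X_all.to_numpy())) or not np.all(np.isfinite(y)):
        raise ValueError("response and covariates must be finite")

    selected: list[str] = []
    history: list[str] = []

    def fit(terms: list[str]):
        X = sm.add_constant(X_all[terms], has_constant="add")
        return sm.OLS(y, X).fit()

    while True:
        remaining = [c for c in covariates if c not in selected]
        best, best_p = None, np.inf
        n_tested = 0
        for cand in remaining:
            trial = selected + [cand]
            X = sm.add_constant(X_all[trial], has_constant="add")
            if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
                history.append(f"skip {cand}: collinear with current model")
                continue
            n_tested += 1
            res = sm.OLS(y, X).fit()
            pv = res.pvalues[cand]
            if not np.isfinite(pv):
                pv = 1.0
            if pv < best_p:
                best, best_p = cand, pv
        threshold = alpha_enter / max(n_tested, 1) if adjust_entry else alpha_enter
        if best is None or best_p >= threshold:
            break
        selected.append(best)
        history.append(f"enter {best} (p={best_p:.4g})")
        # backward check
        while len(selected) > 0:
            res = fit(selected)
            pvals = res.pvalues.drop("const")
            worst = pvals.idxmax()
            if pvals[worst] > alpha_remove:
                selected.remove(worst)
                history.append(f"remove {worst} (p={pvals[worst]:.4g})")
            else:
                break

    if selected:
        res = fit(selected)
        return StepwiseResult(
            terms=list(selected),
            params=res.params,
            pvalues=res.pvalues,
            model=res,
            history=history,
        )
    return StepwiseResult(
        terms=[],
        params=pd.Series(dtype=float),
        pvalues=pd.Series(dtype=float),
        model=None,
        history=history,
    )
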