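"""Paired binary designs and the two surface-water response models.

Model (a) asks whether the surface water of a residence area changes after
the bird leaves: presence days (response 0) are paired with the same
locations re-sampled over the week after abandonment (response 1), with the
daily mean NDWI as covariate, entered as a degree-2 orthogonal polynomial
(the change can go either way, so the relationship need not be monotone).

Model (b) asks whether newly selected areas have the surface water of the
ones just left: the last week before abandoning an area (response 0) is
paired with the first week after arriving at the bird's *next* area
(response 1), NDWI entered linearly.

Both models use random intercepts for year and for area nested within bird
(area levels are keyed bird x area so equal ordinals never pool across
birds), plus a bird-level intercept for the nesting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glmm import GlmmFit, OrthoPolyBasis, fit_binomial_glmm, predict_response_curve
from .water import NdwiSample

DESIGN_COLUMNS = ["response", "ndwi", "bird_id", "area_key", "year", "phase", "date"]


def build_design(samples: list[NdwiSample] | pd.DataFrame, model: str) -> pd.DataFrame:
    """Assemble the paired observation table for model ``"a"`` or ``"b"``.

    Model a: per area, ``presence`` rows (0) and ``post_abandonment`` rows
    (1).  Model b: per consecutive pair of areas of one bird within one
    year, the earlier area's ``pre_abandonment_week`` rows (0) and the later
    area's ``post_arrival_week`` rows (1); areas without a successor are
    dropped from the pairing.
    """
    if model not in ("a", "b"):
        raise ValueError("model must be 'a' or 'b'")
    if isinstance(samples, pd.DataFrame):
        df = samples.copy()
    else:
        from .water import samples_to_frame

        df = samples_to_frame(samples)
    if df.empty:
        return pd.DataFrame(columns=DESIGN_COLUMNS)
    # Season year (May-to-April): keeps an area's early-January
    # post-abandonment samples in the same year level as the area itself,
    # and disambiguates per-year area ordinals.
    df["year"] = df["date"].map(lambda d: d.year if d.month >= 5 else d.year - 1)
    df["area_key"] = (
        df["bird_id"].astype(str)
        + ":"
        + df["year"].astype(str)
        + ":"
        + df["area_id"].astype(str)
    )

    def emit(rows: pd.DataFrame, response: int) -> pd.DataFrame:
        out = rows[["ndwi", "bird_id", "area_key", "year", "phase", "date"]].copy()
        out.insert(0, "response", response)
        return out

    df = df.rename(columns={"daily_mean_ndwi": "ndwi"})
    parts: list[pd.DataFrame] = []
    if model == "a":
        parts.append(emit(df[df["phase"] == "presence"], 0))
        parts.append(emit(df[df["phase"] == "post_abandonment"], 1))
    else:
        # Successor = next area_id of the same bird in the same season year.
        order = (
            df[df["phase"] == "presence"]
            .groupby(["bird_id", "year", "area_id"])["date"]
            .min()
            .reset_index()
            .sort_values(["bird_id", "year", "date"], kind="stable")
        )
        for (bird, year), grp in order.groupby(["bird_id", "year"], sort=False):
            ids = grp["area_id"].tolist()
            for earlier, later in zip(ids[:-1], ids[1:]):
                pre = df[
                    (df["bird_id"] == bird)
                    & (df["year"] == year)
                    & (df["area_id"] == earlier)
                    & (df["phase"] == "pre_abandonment_week")
                ]
                post = df[
                    (df["bird_id"] == bird)
                    & (df["year"] == year)
                    & (df["area_id"] == later)
                    & (df["phase"] == "post_arrival_week")
                ]
                if pre.empty or post.empty:
                    continue
                parts.append(emit(pre, 0))
                parts.append(emit(post, 1))
    if not parts:
        return pd.DataFrame(columns=DESIGN_COLUMNS)
    out = pd.concat(parts, ignore_index=True)
    return out[DESIGN_COLUMNS]


@dataclass
class WaterModelResult:
    model: str
    fit: GlmmFit
    basis: OrthoPolyBasis | None
    design: pd.DataFrame

    def report(self) -> dict:
        """JSON-able fit report mirroring the standard mixed-model table."""
        table = [
            {
                "term": t,
                "estimate": float(b),
                "se": float(s),
                "z": float(z),
                "p": float(p),
            }
            for t, b, s, z, p in zip(
                self.fit.terms, self.fit.beta, self.fit.se, self.fit.z, self.fit.p
            )
        ]
        return {
            "model": self.model,
            "n_obs": self.fit.n_obs,
            "fixed_effects": table,
            "random_intercept_variances": self.fit.variances,
            "marginal_r2": self.fit.marginal_r2,
            "conditional_r2": self.fit.conditional_r2,
            "converged": self.fit.converged,
            "laplace_deviance": self.fit.laplace_deviance,
            "optimizer": self.fit.optimizer,
            "dropped_random_factors": self.fit.dropped_factors,
        }


def fit_water_model(design: pd.DataFrame, model: str, maxfev: int = 400) -> WaterModelResult:
    """Fit model a (poly-2 NDWI) or model b (linear NDWI) on a design table."""
    if model not in ("a", "b"):
        raise ValueError("model must be 'a' or 'b'")
    if design.empty:
        raise ValueError("empty design")
    y = design["response"].to_numpy()
    x = design["ndwi"].to_numpy(dtype=float)
    basis = None
    if model == "a":
        basis = OrthoPolyBasis.fit(x, degree=2)
        X = np.column_stack([np.ones(len(x)), basis.transform(x)])
        terms = ["(Intercept)", "ndwi_poly1", "ndwi_poly2"]
    else:
        X = np.column_stack([np.ones(len(x)), x])
        terms = ["(Intercept)", "ndwi"]
    groups = {
        "year": design["year"].to_numpy(),
        "bird": design["bird_id"].to_numpy(),
        "bird_area": design["area_key"].to_numpy(),
    }
    fit = fit_binomial_glmm(y, X, groups, term_names=terms, maxfev=maxfev)
    fit.x_range = (float(x.min()), float(x.max()))
    return WaterModelResult(model=model, fit=fit, basis=basis, design=design)


def response_curve(result: WaterModelResult, ndwi_grid: np.ndarray) -> pd.DataFrame:
    """Predicted probability ± 95% CI over an NDWI grid (random effects 0)."""
    grid = np.asarray(ndwi_grid, dtype=float)
    if result.basis is not None:
        Xg = np.column_stack([np.ones(len(grid)), result.basis.transform(grid)])
    else:
        Xg = np.column_stack([np.ones(len(grid)), grid])
    return predict_response_curve(result.fit, Xg, x_values=grid)
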