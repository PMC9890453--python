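"""Linear mixed models for single-trial amplitudes, statsmodels-style.

:class:`SingleTrialLMM` is the model object: it holds an amplitude table,
the fixed factors (sum-coded, with full interactions) and a requested random
structure with crossed participant and stimulus terms.  ``fit()`` runs the
parsimonious random-structure selection ladder and returns a
:class:`LMMResults`, which exposes estimated marginal means, pairwise
contrasts and pairwise interaction contrasts, each carrying NHST and
equivalence-test verdicts.

Crossed random effects are fitted as variance components (one variance per
term, no cross-term correlations), so the ladder's zero-correlation rung
coincides with the maximal model and its "extended" rung with the reduced
model; the term-dropping and AIC rungs are real and every rung is logged in
``LMMResults.ladder_trace``.

The selection ladder:

1. fit the maximal requested structure (REML);
2. drop random terms that do not contribute — likelihood-ratio p > 0.2 on
   ML refits, or a variance below 1e-4 of the residual variance — one at a
   time, least contributing first (the reduced model);
3. if a rung fails to converge, drop the smallest-variance term and retry;
4. choose between the reduced model and the last converged larger model by
   ML AIC.

Degrees of freedom for contrasts are residual df (the backend does not
supply a Satterthwaite approximation); every contrast is tagged with the df
method used.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import build_design_matrices
from scipy import stats
import statsmodels.formula.api as smf

from .equivalence import ContrastResult, EquivalenceRegion


@dataclass(frozen=True)
class RandomStructure:
    """Requested random-effect terms (crossed participant x stimulus)."""

    participant_intercept: bool = True
    stimulus_intercept: bool = True
    participant_slopes: tuple = ()
    stimulus_slopes: tuple = ()

    def terms(self, participant_col: str, stimulus_col: str) -> dict[str, str]:
        t: dict[str, str] = {}
        if self.participant_intercept:
            t["participant"] = f"0 + C({participant_col})"
        if self.stimulus_intercept:
            t["stimulus"] = f"0 + C({stimulus_col})"
        for f in self.participant_slopes:
            t[f"participant_x_{f}"] = f"0 + C({participant_col}):C({f}, Sum)"
        for f in self.stimulus_slopes:
            t[f"stimulus_x_{f}"] = f"0 + C({stimulus_col}):C({f}, Sum)"
        return t


@dataclass
class LadderRung:
    """One step of the random-structure selection ladder."""

    name: str
    terms: tuple
    converged: bool
    loglike: float = np.nan
    aic: float = np.nan
    note: str = ""


class _OLSAsMixed:
    """Adapter presenting an OLS fit through the MixedLM results surface,
    for the ladder rung where no random term survives."""

    def __init__(self, res):
        self._res = res
        self.fe_params = np.asarray(res.params)
        self.params = np.asarray(res.params)
        self.vcomp = np.array([])
        self.scale = float(res.scale)
        self.converged = True
        self.llf = float(res.llf)

    def cov_params(self):
        return np.asarray(self._res.cov_params())


class SingleTrialLMM:
    """Mixed model for a single-trial mean-amplitude table.

    Parameters
    ----------
    data : DataFrame with one row per observation.
    response : name of the amplitude column (uV).
    factors : fixed factors, fitted sum-coded with full interactions.
    random : requested random structure (the ladder prunes it).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        response: str = "mean_amplitude",
        factors: tuple = ("duration",),
        random: RandomStructure = RandomStructure(),
        participant_col: str = "participant_id",
        stimulus_col: str = "stimulus_id",
    ):
        cols = [response, participant_col, stimulus_col, *factors]
        data = data.dropna(subset=cols).reset_index(drop=True)
        if data[participant_col].nunique() < 2:
            raise ValueError("need at least 2 participants")
        if data[stimulus_col].nunique() < 2:
            raise ValueError("need at least 2 stimuli")
        for f in factors:
            if data[f].nunique() < 2:
                raise ValueError(f"factor {f!r} is degenerate (single level)")
        self.data = data
        self.response = response
        self.factors = tuple(factors)
        self.random = random
        self.participant_col = participant_col
        self.stimulus_col = stimulus_col
        self.levels = {f: sorted(data[f].unique().tolist()) for f in factors}
        self.formula = response + " ~ " + " * ".join(
            f"C({f}, Sum)" for f in factors
        )

    @classmethod
    def from_amplitude_table(
        cls,
        table: pd.DataFrame,
        component: str,
        factors: tuple,
        **kwargs,
    ) -> "SingleTrialLMM":
        """Build a model from a long amplitude table for one component."""
        sub = table[table["component"] == component]
        return cls(sub, factors=factors, **kwargs)

    # -- fitting -------------------------------------------------------
    def _fit_once(self, term_names: tuple, reml: bool):
        all_terms = self.random.terms(self.participant_col, self.stimulus_col)
        vc = {k: all_terms[k] for k in term_names}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if vc:
                m = smf.mixedlm(
                    self.formula,
                    self.data,
                    groups=np.ones(len(self.data)),
                    vc_formula=vc,
                    re_formula="0",
                )
                res = m.fit(reml=reml, method="lbfgs", maxiter=200)
                converged = bool(res.converged) and bool(np.isfinite(res.params).all())
            else:
                # every random term dropped: the model degenerates to OLS
                m = smf.ols(self.formula, self.data)
                res = _OLSAsMixed(m.fit())
                converged = True
        return m, res, converged

    def _ml_loglike(self, term_names: tuple) -> tuple[float, float, bool]:
        _, res, conv = self._fit_once(term_names, reml=False)
        k = len(res.params)
        ll = float(res.llf)
        return ll, 2 * k - 2 * ll, conv

    def fit(
        self,
        lrt_threshold: float = 0.2,
        var_floor: float = 1e-4,
    ) -> "LMMResults":
        """Run the selection ladder and return results for the optimal model."""
        all_terms = tuple(
            self.random.terms(self.participant_col, self.stimulus_col)
        )
        trace: list[LadderRung] = []

        def rung(name, terms, note=""):
            m, res, conv = self._fit_once(terms, reml=True)
            ll, aic, _ = (np.nan, np.nan, False)
            if conv:
                ll, aic, _ = self._ml_loglike(terms)
            trace.append(LadderRung(name, terms, conv, ll, aic, note))
            return m, res, conv

        terms = all_terms
        m, res, conv = rung(
            "maximal",
            terms,
            "zero-correlation parameterization: maximal == ZCP model",
        )
        # non-convergence: drop smallest-variance terms one by one
        while not conv and terms:
            vnames = list(terms)
            v = res.vcomp if res is not None else np.zeros(len(vnames))
            drop = vnames[int(np.argmin(v))] if len(v) == len(vnames) else vnames[-1]
            terms = tuple(t for t in terms if t != drop)
            m, res, conv = rung(
                f"drop_for_convergence[{drop}]", terms, "smallest variance dropped"
            )
        if not conv:
            raise RuntimeError(
                "no rung of the selection ladder converged; trace: "
                + "; ".join(f"{r.name}({r.terms})" for r in trace)
            )
        last_converged = (m, res, terms)

        # reduced model: remove non-contributing terms (LRT on ML fits or
        # variance below the floor), least contributing first
        terms_red = terms
        ll_full, _, _ = self._ml_loglike(terms_red)
        changed = True
        while changed and terms_red:
            changed = False
            _, res_r, _ = self._fit_once(terms_red, reml=True)
            vnames = list(terms_red)
            vcomp = dict(zip(vnames, res_r.vcomp))
            floor = var_floor * res_r.scale
            candidates = []
            for t in vnames:
                if vcomp[t] < floor:
                    candidates.append((t, 1.0, "variance below floor"))
                    continue
                sub = tuple(x for x in terms_red if x != t)
                ll_sub, _, conv_sub = self._ml_loglike(sub)
                if not conv_sub:
                    continue
                lr = max(0.0, 2 * (ll_full - ll_sub))
                p = stats.chi2.sf(lr, df=1)
                if p > lrt_threshold:
                    candidates.append((t, p, f"LRT p={p:.3f} > {lrt_threshold}"))
            if candidates:
                t, p, why = max(candidates, key=lambda c: c[1])
                terms_red = tuple(x for x in terms_red if x != t)
                ll_full, _, _ = self._ml_loglike(terms_red)
                trace.append(
                    LadderRung(f"reduce[{t}]", terms_red, True, ll_full, note=why)
                )
                changed = True

        m_red, res_red, conv_red = self._fit_once(terms_red, reml=True)
        _, aic_red, _ = self._ml_loglike(terms_red)
        trace.append(
            LadderRung(
                "reduced/extended",
                terms_red,
                conv_red,
                aic=aic_red,
                note="extended == reduced under the variance-component "
                "parameterization (no cross-term correlations)",
            )
        )

        # optimal: smaller ML AIC between reduced and last converged larger model
        _, aic_big, _ = self._ml_loglike(last_converged[2])
        if terms_red != last_converged[2] and aic_big <= aic_red:
            m_opt, res_opt, terms_opt, which = (*last_converged[:2], last_converged[2], "larger")
        else:
            m_opt, res_opt, terms_opt, which = m_red, res_red, terms_red, "reduced"
        trace.append(
            LadderRung(
                "optimal",
                terms_opt,
                True,
                aic=min(aic_big, aic_red),
                note=f"selected the {which} model by ML AIC "
                f"(reduced={aic_red:.2f}, larger={aic_big:.2f})",
            )
        )
        return LMMResults(self, m_opt, res_opt, terms_opt, trace)


class LMMResults:
    """Results of the optimal mixed model, with emmeans-style follow-ups."""

    df_method = "residual"

    def __init__(self, model, sm_model, sm_result, terms, ladder_trace):
        self.model = model
        self._sm_model = sm_model
        self._sm_result = sm_result
        self.random_terms = terms
        self.ladder_trace = ladder_trace
        self.fe_params = np.asarray(sm_result.fe_params)
        k = len(self.fe_params)
        self.cov_fe = np.asarray(sm_result.cov_params())[:k, :k]
        self.vcomp = dict(zip(terms, np.asarray(sm_result.vcomp)))
        self.scale = float(sm_result.scale)
        self.converged = bool(sm_result.converged)
        n = len(model.data)
        self.df_resid = float(n - k)
        self._design_info = sm_model.data.design_info

    # -- estimated marginal means -------------------------------------
    def _grid_rows(self) -> pd.DataFrame:
        combos = list(itertools.product(*[self.model.levels[f] for f in self.model.factors]))
        return pd.DataFrame(combos, columns=list(self.model.factors))

    def _cell_L(self, cell: dict) -> np.ndarray:
        """Model-matrix row for a cell, averaging uniformly over the levels
        of every factor not fixed by ``cell``."""
        grid = self._grid_rows()
        for f, lev in cell.items():
            grid = grid[grid[f] == lev]
        if len(grid) == 0:
            raise ValueError(f"rank-deficient or empty grid request: {cell}")
        X = np.asarray(build_design_matrices([self._design_info], grid)[0])
        return X.mean(axis=0)

    def emmeans(self, factors: tuple | list) -> pd.DataFrame:
        """Model-based cell means for a factor grid, with SEs.

        Non-focal factors are averaged uniformly over their levels.
        """
        factors = list(factors)
        for f in factors:
            if f not in self.model.factors:
                raise ValueError(f"factor {f!r} not in the model")
        if factors:
            cells = [
                dict(zip(factors, combo))
                for combo in itertools.product(*[self.model.levels[f] for f in factors])
            ]
        else:
            cells = [{}]
        rows = []
        for cell in cells:
            L = self._cell_L(cell)
            mean = float(L @ self.fe_params)
            se = float(np.sqrt(L @ self.cov_fe @ L))
            rows.append({**cell, "emmean": mean, "SE": se})
        return pd.DataFrame(rows)

    # -- contrasts -----------------------------------------------------
    def _contrast(self, L: np.ndarray, label: str, region, family) -> ContrastResult:
        b = float(L @ self.fe_params)
        se = float(np.sqrt(L @ self.cov_fe @ L))
        return ContrastResult.from_estimate(
            label, b, se, self.df_resid,
            region=region, family=family, df_method=self.df_method,
        )

    def pairwise(
        self,
        focal: str,
        by: tuple = (),
        family: int = 1,
        region: EquivalenceRegion = EquivalenceRegion(),
    ) -> list[ContrastResult]:
        """All pairwise differences between levels of ``focal``, within each
        cell of the ``by`` factors, Bonferroni-corrected by ``family``."""
        levels = self.model.levels[focal]
        pairs = list(itertools.combinations(levels, 2))
        if family < len(pairs):
            raise ValueError(
                f"family size {family} is smaller than the {len(pairs)} "
                f"pairwise tests per cell"
            )
        by = list(by)
        by_cells = (
            [dict(zip(by, c)) for c in itertools.product(*[self.model.levels[f] for f in by])]
            if by
            else [{}]
        )
        out = []
        for cell in by_cells:
            for l1, l2 in pairs:
                L = self._cell_L({**cell, focal: l1}) - self._cell_L({**cell, focal: l2})
                suffix = (
                    " | " + ", ".join(f"{k}={v}" for k, v in cell.items()) if cell else ""
                )
                out.append(
                    self._contrast(L, f"{focal}: {l1} - {l2}{suffix}", region, family)
                )
        return out

    def interaction_contrasts(
        self,
        factor_a: str,
        factor_b: str,
        by: tuple = (),
        family: int = 1,
        levels_a: tuple | None = None,
        region: EquivalenceRegion = EquivalenceRegion(),
    ) -> list[ContrastResult]:
        """Pairwise interaction contrasts (differences of differences).

        For the two selected levels (a1, a2) of ``factor_a`` and every pair
        (b1, b2) of ``factor_b`` levels, computes
        (a1,b1 - a2,b1) - (a1,b2 - a2,b2), e.g.
        (33 ms faces - 33 ms houses) - (216 ms faces - 216 ms houses).
        """
        la = list(levels_a) if levels_a is not None else self.model.levels[factor_a]
        if len(la) != 2:
            raise ValueError("factor_a must have exactly 2 selected levels")
        a1, a2 = la
        pairs = list(itertools.combinations(self.model.levels[factor_b], 2))
        if family < len(pairs):
            raise ValueError(
                f"family size {family} is smaller than the {len(pairs)} "
                f"interaction contrasts per cell"
            )
        by = list(by)
        by_cells = (
            [dict(zip(by, c)) for c in itertools.product(*[self.model.levels[f] for f in by])]
            if by
            else [{}]
        )
        out = []
        for cell in by_cells:
            for b1, b2 in pairs:
                L = (
                    self._cell_L({**cell, factor_a: a1, factor_b: b1})
                    - self._cell_L({**cell, factor_a: a2, factor_b: b1})
                    - self._cell_L({**cell, factor_a: a1, factor_b: b2})
                    + self._cell_L({**cell, factor_a: a2, factor_b: b2})
                )
                suffix = (
                    " | " + ", ".join(f"{k}={v}" for k, v in cell.items()) if cell else ""
                )
                out.append(
                    self._contrast(
                        L,
                        f"({factor_a}:{a1}-{a2}) x ({factor_b}:{b1}-{b2}){suffix}",
                        region,
                        family,
                    )
                )
        return out

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Single-trial amplitude mixed model",
            f"  response: {self.model.response}",
            f"  fixed factors (sum-coded, full interactions): {', '.join(self.model.factors)}",
            f"  random terms: {', '.join(self.random_terms) or '(none)'}",
            f"  n obs: {len(self.model.data)}, residual df: {self.df_resid:.0f} "
            f"(df method: {self.df_method})",
            "",
            "  variance components (uV^2):",
        ]
        for t, v in self.vcomp.items():
            lines.append(f"    {t:<28s} {v:10.4f}")
        lines.append(f"    {'residual':<28s} {self.scale:10.4f}")
        lines.append("")
        lines.append("  ladder:")
        for r in self.ladder_trace:
            aic = f"AIC={r.aic:.2f}" if np.isfinite(r.aic) else "AIC=n/a"
            lines.append(
                f"    {r.name:<28s} terms={list(r.terms)} "
                f"converged={r.converged} {aic} {r.note}"
            )
        return "\n".join(lines)
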