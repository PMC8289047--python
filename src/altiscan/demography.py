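"""Composite-likelihood demographic inference from the folded joint SFS.

Eight nested demographic hypotheses are fitted to a folded two-dimensional
SFS by expectation–conditional-maximization (ECM) of a multinomial composite
likelihood, with the expected SFS obtained by Monte-Carlo coalescent
simulation under common random numbers.  Models:

======  =====================================================================
 M1     single panmictic population, constant size
 M2     single population with one instantaneous size change
 M3     split, unidirectional gene flow lowland -> highland
 M4     split, unidirectional gene flow highland -> lowland
 M5     split, bidirectional gene flow
 M6–M8  as M3–M5 with founder-size changes in both daughter populations
======  =====================================================================

Usage follows the Model/Results pattern::

    model = SFSDemographyModel(observed_sfs, model="M3")
    res = model.fit(seed=1)
    print(res.summary())
    ci = res.bootstrap_ci(n_boot=100, seed=2)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .sfs import JointSFS, fold_cell
from .simulate import expected_sfs, _kernel_seed, _stream_seed

from .types import DemographySpec, DEFAULT_MU

__all__ = [
    "ModelSpec",
    "MODELS",
    "composite_loglik",
    "SFSDemographyModel",
    "SFSDemographyResults",
    "compare_models",
    "years_from_generations",
]


def years_from_generations(gens: float, gen_time_years: float = 1.0) -> float:
    """Convert a time in generations to years."""
    if gens < 0:
        raise ValueError("generations must be >= 0")
    return gens * gen_time_years


# ----------------------------------------------------------------------
# model definitions

_SIZE_B = (2.0, 7.0)      # log10 diploid size
# migrants per generation, log10.  The upper bound (~3.2) is a generous
# prior: sustained gene flow beyond a few migrant lineages per generation
# drives FST toward zero at these divergence levels, and it regularizes the
# isolation-vs-migration likelihood ridge (see docs/methods.md) while
# keeping worst-case simulation cost bounded (event counts scale with the
# migration rate).
_MIG_B = (-4.0, 0.5)
_TIME_B = (1.0, 6.0)      # log10 generations
_FRAC_B = (0.05, 0.95)    # linear, resize time as a fraction of T_split


@dataclass(frozen=True)
class ModelSpec:
    """A demographic hypothesis: free parameters, bounds, and a builder."""

    model_id: str
    param_names: tuple
    bounds: tuple           # in transformed (mostly log10) space
    log_scale: tuple        # per-parameter flag

    @property
    def k(self) -> int:
        return len(self.param_names)

    def transform(self, values: dict) -> np.ndarray:
        out = []
        for name, log in zip(self.param_names, self.log_scale):
            v = values[name]
            out.append(np.log10(v) if log else v)
        return np.asarray(out, dtype=float)

    def untransform(self, x: np.ndarray) -> dict:
        return {
            name: (10.0 ** xi if log else xi)
            for name, xi, log in zip(self.param_names, x, self.log_scale)
        }

    def build_spec(self, values: dict, mu: float = DEFAULT_MU) -> DemographySpec:
        mid = self.model_id
        if mid == "M1":
            return DemographySpec(n_pops=1, N_high=values["N"], mu=mu)
        if mid == "M2":
            return DemographySpec(
                n_pops=1, N_high=values["N_cur"], mu=mu,
                size_changes=((values["T_change"], "high", values["N_anc"]),),
            )
        kw = dict(
            n_pops=2,
            N_high=values["N_high"],
            N_low=values["N_low"],
            N_anc=values["N_anc"],
            T_split=values["T_split"],
            mu=mu,
            m_low_to_high=values.get("M_lh", 0.0),
            m_high_to_low=values.get("M_hl", 0.0),
        )
        if mid in ("M6", "M7", "M8"):
            t_resize = values["resize_frac"] * values["T_split"]
            kw["size_changes"] = (
                (t_resize, "high", values["N_high_0"]),
                (t_resize, "low", values["N_low_0"]),
            )
        return DemographySpec(**kw)


def _make_models() -> dict:
    models = {}
    models["M1"] = ModelSpec("M1", ("N",), (_SIZE_B,), (True,))
    models["M2"] = ModelSpec(
        "M2", ("N_cur", "N_anc", "T_change"),
        (_SIZE_B, _SIZE_B, _TIME_B), (True, True, True),
    )
    split_names = ("N_high", "N_low", "N_anc", "T_split")
    split_bounds = (_SIZE_B, _SIZE_B, _SIZE_B, _TIME_B)
    split_logs = (True, True, True, True)
    mig = {"M3": ("M_lh",), "M4": ("M_hl",), "M5": ("M_lh", "M_hl")}
    for mid, extra in mig.items():
        models[mid] = ModelSpec(
            mid, split_names + extra,
            split_bounds + tuple(_MIG_B for _ in extra),
            split_logs + tuple(True for _ in extra),
        )
    resize_names = ("N_high_0", "N_low_0", "resize_frac")
    resize_bounds = (_SIZE_B, _SIZE_B, _FRAC_B)
    resize_logs = (True, True, False)
    for base, mid in (("M3", "M6"), ("M4", "M7"), ("M5", "M8")):
        b = models[base]
        models[mid] = ModelSpec(
            mid, b.param_names + resize_names,
            b.bounds + resize_bounds, b.log_scale + resize_logs,
        )
    return models


MODELS = _make_models()


# ----------------------------------------------------------------------
# composite likelihood


def composite_loglik(observed: JointSFS, expected: JointSFS,
                     min_prop: float = 1e-8) -> float:
    """Multinomial composite log-likelihood sum(obs * log(expected prop)).

    ``observed`` must be in count mode and ``expected`` in proportion mode on
    matching sample sizes; expected proportions are floored at ``min_prop``
    to keep empty cells finite.
    """
    if (observed.n1, observed.n2) != (expected.n1, expected.n2):
        raise ValueError("observed and expected SFS sample sizes differ")
    if not observed.counts or expected.counts:
        raise ValueError("need observed counts and expected proportions")
    mask = observed.segregating_mask()
    obs = observed.data[mask]
    exp_ = np.maximum(expected.data[mask], min_prop)
    return float(np.sum(obs * np.log(exp_)))


# ----------------------------------------------------------------------
# results object


@dataclass
class SFSDemographyResults:
    """Fit results: point estimates, composite logL, AIC, optimizer trace."""

    model: "SFSDemographyModel"
    model_id: str
    params: dict
    spec: DemographySpec
    llf: float
    nobs: float
    seed: int
    converged: bool
    cycles: int
    trace: list = field(default_factory=list)
    restart_llfs: list = field(default_factory=list)
    eval_draws: int = 0

    @property
    def k(self) -> int:
        """Free-parameter count entering the AIC."""
        return len(self.model.free_names)

    @property
    def aic(self) -> float:
        return 2 * self.k - 2 * self.llf

    def summary(self) -> str:
        lines = [
            f"SFS demographic fit — model {self.model_id}",
            f"  segregating sites: {self.nobs:.0f}",
            f"  composite logL: {self.llf:.2f}   AIC: {self.aic:.2f}   "
            f"k: {self.k}",
            f"  ECM cycles: {self.cycles}   converged: {self.converged}",
            "  parameters:",
        ]
        for name, v in self.params.items():
            lines.append(f"    {name:12s} {v:>14.6g}")
        if "T_split" in self.params:
            yrs = years_from_generations(
                self.params["T_split"], self.spec.gen_time_years
            )
            lines.append(f"    (T_split = {yrs:.0f} years at "
                         f"{self.spec.gen_time_years:g} yr/generation)")
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def bootstrap_ci(self, n_boot: int = 100, seed: int = 0,
                     **fit_kwargs) -> pd.DataFrame:
        """Parametric bootstrap CIs.

        Simulates ``n_boot`` fresh SFS replicates (same number of segregating
        sites as observed) under the point estimates, refits each starting at
        the point estimates, and returns per-parameter mean and empirical
        2.5/97.5 percentiles.  Replicates that fail to refit are recorded and
        excluded.
        """
        mdl = self.model
        n_sites = int(round(self.nobs))
        reps = {name: [] for name in mdl.free_names}
        failures = 0
        fit_kwargs.setdefault("n_restarts", 1)
        fit_kwargs.setdefault("min_cycles", 3)
        fit_kwargs.setdefault("max_cycles", mdl_default_max(fit_kwargs))
        for b in range(n_boot):
            boot_seed = _kernel_seed(seed + 7919 * (b + 1))
            sfs_b = simulate_sfs_counts(
                self.spec, mdl.observed.n1, mdl.observed.n2, n_sites, boot_seed
            )
            try:
                m_b = SFSDemographyModel(
                    sfs_b, model=self.model_id, mu=mdl.mu,
                    n_draws=mdl.n_draws, min_prop=mdl.min_prop,
                    fixed=mdl.fixed,
                )
                r_b = m_b.fit(seed=boot_seed, start=self.params, **fit_kwargs)
            except Exception:  # pragma: no cover - defensive
                failures += 1
                continue
            for name in reps:
                reps[name].append(r_b.params[name])
        if failures:
            warnings.warn(f"{failures} bootstrap replicates failed to converge")
        rows = []
        for name, vals in reps.items():
            v = np.asarray(vals, dtype=float)
            rows.append({
                "parameter": name,
                "estimate": self.params[name],
                "boot_mean": v.mean() if v.size else np.nan,
                "ci_low": np.percentile(v, 2.5) if v.size else np.nan,
                "ci_high": np.percentile(v, 97.5) if v.size else np.nan,
                "n_boot": int(v.size),
                "low_confidence": bool(v.size < 20),
            })
        return pd.DataFrame(rows)


def mdl_default_max(fit_kwargs) -> int:
    return max(10, 2 * fit_kwargs.get("min_cycles", 3))


def simulate_sfs_counts(spec: DemographySpec, n1: int, n2: int,
                        n_sites: int, seed: int) -> JointSFS:
    """Simulate a folded joint SFS of ``n_sites`` unlinked segregating sites."""
    from .simulate import sample_unlinked_carriers
    carriers = sample_unlinked_carriers(
        spec.to_epochs(), n1, n2, int(n_sites), _stream_seed(seed, "sfs_counts")
    )
    c1 = carriers[:, :n1].sum(axis=1)
    c2 = carriers[:, n1:].sum(axis=1)
    data = np.zeros((n1 + 1, n2 + 1))
    for i, j in zip(c1, c2):
        fi, fj = fold_cell(int(i), int(j), n1, n2)
        data[fi, fj] += 1
    return JointSFS(data, n1, n2, counts=True)


# ----------------------------------------------------------------------
# optimizer coordinates
#
# The folded-SFS shape is (nearly) invariant under a joint rescaling of all
# sizes and times, so the natural parameters (T_split, N_high, ...) form a
# diagonal likelihood ridge that one-parameter-at-a-time maximization cannot
# follow.  The ECM therefore works in ridge-aligned coordinates: daughter-deme
# sizes are replaced by drift amounts T_split/(2N) whenever the split time is
# itself free, so a 1-D move in T explores the ridge with the strongly
# identified drift (and migrant-dose) combinations held fixed.

_DRIFT_B = (-4.0, 0.7)


def _opt_coords(mspec: ModelSpec, fixed: dict):
    free = [n for n in mspec.param_names if n not in fixed]
    t_free = "T_split" in free
    coords = []   # (coord name, natural name, bounds)
    for n in free:
        if n == "N_high" and t_free:
            coords.append(("drift_high", n, _DRIFT_B))
        elif n == "N_low" and t_free:
            coords.append(("drift_low", n, _DRIFT_B))
        elif n in ("M_lh", "M_hl"):
            coords.append((n, n, _MIG_B))
        elif n in ("T_split", "T_change"):
            coords.append((n, n, _TIME_B))
        elif n == "resize_frac":
            coords.append((n, n, _FRAC_B))
        else:
            coords.append((n, n, _SIZE_B))
    cnames = [c for c, _, _ in coords]

    def decode(x) -> dict:
        values = dict(fixed)
        xm = dict(zip(cnames, x))
        for c, n, _ in coords:
            if c == "resize_frac":
                values[n] = xm[c]
            elif not c.startswith("drift_"):
                values[n] = 10.0 ** xm[c]
        T = values.get("T_split", 0.0)
        for c, n, _ in coords:
            if c.startswith("drift_"):
                values[n] = T / (2.0 * 10.0 ** xm[c])
        return values

    def encode(values: dict) -> np.ndarray:
        out = []
        T = values.get("T_split", 0.0)
        for c, n, _ in coords:
            if c == "resize_frac":
                out.append(values[n])
            elif c.startswith("drift_"):
                out.append(np.log10(T / (2.0 * values[n])))
            else:
                out.append(np.log10(values[n]))
        return np.asarray(out, dtype=float)

    bounds = [b for _, _, b in coords]
    return cnames, bounds, decode, encode


# ----------------------------------------------------------------------
# the model


class SFSDemographyModel:
    """Composite-likelihood SFS model, statsmodels-style.

    Parameters
    ----------
    observed
        Folded joint SFS in count mode.
    model
        One of ``"M1"..."M8"``.
    mu
        Mutation rate (enters only through reporting conventions; the
        conditional-on-segregating multinomial likelihood is scale-free).
    n_draws
        Genealogy replicates per expected-SFS evaluation during optimization.
        Each genealogy contributes its full branch-length profile, so the
        effective number of site draws is far larger.
    min_prop
        Floor on expected cell proportions (guards ``log 0``).
    fixed
        Parameters held at given values rather than estimated.  The
        conditional-on-segregating-sites likelihood depends only on the shape
        of the SFS, which is invariant under a joint rescaling of all sizes
        and times: absolute times are identified only once at least one
        population size is pinned (e.g. the nuisance lowland/ancestral
        sizes).  Fixed parameters do not count toward AIC's ``k``.
    """

    def __init__(self, observed: JointSFS, model: str = "M3",
                 mu: float = DEFAULT_MU, n_draws: int = 10_000,
                 min_prop: float = 1e-8, fixed: dict = None):
        if model not in MODELS:
            raise ValueError(f"unknown model {model!r}")
        if not observed.counts:
            raise ValueError("observed SFS must be in count mode")
        if observed.total < 1:
            raise ValueError("observed SFS has no segregating sites")
        self.observed = observed
        self.model_id = model
        self.mspec = MODELS[model]
        self.mu = mu
        self.n_draws = int(n_draws)
        self.min_prop = float(min_prop)
        self.fixed = dict(fixed or {})
        for name in self.fixed:
            if name not in self.mspec.param_names:
                raise ValueError(f"unknown fixed parameter {name!r}")
        self.free_names = tuple(
            n for n in self.mspec.param_names if n not in self.fixed
        )
        if not self.free_names:
            raise ValueError("at least one parameter must be free")

    @classmethod
    def from_variant_table(cls, vt, model: str = "M3", pops=None, **kwargs):
        from .stats import fold_joint_sfs
        return cls(fold_joint_sfs(vt, pops=pops), model=model, **kwargs)

    # ------------------------------------------------------------------
    def loglike(self, values: dict, seed: int, n_draws: int = None) -> float:
        """Composite logL at a parameter point (CRN stream from ``seed``)."""
        spec = self.mspec.build_spec(values, mu=self.mu)
        exp_sfs = expected_sfs(
            spec, self.observed.n1, self.observed.n2,
            n_draws or self.n_draws, seed,
        )
        return composite_loglik(self.observed, exp_sfs, self.min_prop)

    # ------------------------------------------------------------------
    def fit(self, seed: int = 0, n_restarts: int = 3, min_cycles: int = 20,
            max_cycles: int = 80, tol: float = 1e-2, start: dict = None,
            eval_draws: int = None, xatol: float = 0.02,
            brent_maxiter: int = 10, polish_cycles: int = 3,
            polish_draws: int = None) -> SFSDemographyResults:
        """Expectation–conditional-maximization fit.

        Cycles over the free parameters, maximizing the common-random-number
        composite likelihood one parameter at a time (bounded Brent on the
        transformed scale); a proposed 1-D optimum is accepted only if it
        improves the likelihood, so accepted moves are monotone.  Stops after
        ``min_cycles`` once a full cycle improves the likelihood by less than
        ``tol`` log-units, or at ``max_cycles``.  Runs ``n_restarts``
        independent uniform starting draws and keeps the best; the final
        likelihood is re-evaluated with ``eval_draws`` replicates on the same
        seed-``seed`` stream, so fits of different models at the same seed
        are comparable.
        """
        if min_cycles < 1 or max_cycles < min_cycles:
            raise ValueError("need 1 <= min_cycles <= max_cycles")
        rng = np.random.default_rng(seed)
        crn_seed = _kernel_seed(seed)
        # final likelihoods are evaluated on a stream the optimizer never
        # maximized: in-sample evaluation lets higher-dimensional models climb
        # Monte-Carlo noise and defeat the AIC penalty.  The eval stream is a
        # deterministic function of the user seed, hence common across models.
        eval_seed = _stream_seed(seed, "fit_eval")
        eval_draws = eval_draws or 20 * self.n_draws
        polish_draws = polish_draws or 8 * self.n_draws
        cnames, bounds, decode, encode = _opt_coords(self.mspec, self.fixed)
        mig_idx = [i for i, c in enumerate(cnames) if c in ("M_lh", "M_hl")]

        def ecm_loop(x, f, active, mn, mx):
            """One ECM run over the ``active`` coordinate set; monotone."""
            cur_ll = f(x)
            trace = [cur_ll]
            converged = False
            cycles = 0
            for cycle in range(mx):
                cycles = cycle + 1
                ll_before = cur_ll
                for p in active:
                    lo, hi = bounds[p]

                    def neg(v):
                        xv = x.copy()
                        xv[p] = v
                        return -f(xv)

                    res = minimize_scalar(
                        neg, bounds=(lo, hi), method="bounded",
                        options={"xatol": xatol, "maxiter": brent_maxiter},
                    )
                    xv = x.copy()
                    xv[p] = float(np.clip(res.x, lo, hi))
                    if f(xv) > cur_ll:
                        x = xv
                        cur_ll = f(xv)
                trace.append(cur_ll)
                if cycles >= mn and cur_ll - ll_before < tol:
                    converged = True
                    break
            return x, cur_ll, trace, converged, cycles

        # restart plan: explicit warm start first, then a staged
        # (no-migration-first) start, then fully uniform draws
        kinds = []
        if start is not None:
            kinds.append("start")
        if mig_idx:
            kinds.append("staged")
        while len(kinds) < n_restarts:
            kinds.append("uniform")
        kinds = kinds[:max(n_restarts, 1)]

        best = None
        restart_llfs = []
        n_all = list(range(len(cnames)))
        for kind in kinds:
            cache = {}

            def f(xvec):
                key = tuple(np.round(xvec, 10))
                if key not in cache:
                    cache[key] = self.loglike(decode(np.asarray(xvec)), crn_seed)
                return cache[key]

            x = np.array([rng.uniform(lo, hi) for lo, hi in bounds])
            pre = []
            if kind == "start":
                x = encode({**dict(start), **self.fixed})
                x = np.clip(x, [b[0] for b in bounds], [b[1] for b in bounds])
            elif kind == "staged":
                # staged start: the near-isolation optimum has a narrow basin
                # that plain ECM rarely reaches from a high-migration start,
                # because escaping requires coordinated moves.  Fit the
                # no-migration model first, then release migration.
                for i in mig_idx:
                    x[i] = bounds[i][0]
                nonmig = [p for p in n_all if p not in mig_idx]
                x, _, pre, _, _ = ecm_loop(
                    x, f, nonmig, min(8, min_cycles), min(12, max_cycles)
                )
            x, cur_ll, trace, converged, cycles = ecm_loop(
                x, f, n_all, min_cycles, max_cycles
            )
            trace = pre + trace

            # polish every restart at much higher precision: near-flat ridge
            # directions need low-noise evaluations to resolve, and basins a
            # few log-units apart cannot be compared before each candidate is
            # close to its own basin optimum
            if polish_cycles > 0:
                pcache = {}

                def fp(xvec):
                    key = tuple(np.round(xvec, 10))
                    if key not in pcache:
                        pcache[key] = self.loglike(
                            decode(np.asarray(xvec)), crn_seed,
                            n_draws=polish_draws,
                        )
                    return pcache[key]

                x, _, ptrace, _, _ = ecm_loop(
                    x, fp, n_all, polish_cycles, polish_cycles
                )
                trace = trace + ptrace[1:]

            ll_precise = self.loglike(decode(x), eval_seed, n_draws=eval_draws)
            restart_llfs.append(ll_precise)
            if best is None or ll_precise > best[1]:
                best = (x.copy(), ll_precise, trace, converged, cycles)

        x, llf, trace, converged, cycles = best
        values = decode(x)
        return SFSDemographyResults(
            model=self,
            model_id=self.model_id,
            params=values,
            spec=self.mspec.build_spec(values, mu=self.mu),
            llf=llf,
            nobs=self.observed.total,
            seed=int(seed),
            converged=converged,
            cycles=cycles,
            trace=trace,
            restart_llfs=restart_llfs,
            eval_draws=eval_draws,
        )


# ----------------------------------------------------------------------


#: warm-start sources for nested models (a constrained model's optimum is a
#: legal start for the supermodel, with released parameters at their floor)
_NESTED_PARENTS = {
    "M2": ("M1",), "M4": (), "M5": ("M3", "M4"),
    "M6": ("M3",), "M7": ("M4",), "M8": ("M5",),
}
_RELEASED_FLOORS = {
    "M_lh": 10.0 ** _MIG_B[0], "M_hl": 10.0 ** _MIG_B[0],
    "resize_frac": 0.5,
}


def fit_models(observed: JointSFS, model_ids, seed: int = 0,
               fixed: dict = None, warm_nested: bool = True,
               model_kwargs: dict = None, **fit_kwargs):
    """Fit several models to one SFS and return their results in order.

    With ``warm_nested`` (default), each supermodel also starts from the best
    fitted sub-model already in the list (released parameters at neutral
    floor values), which both speeds convergence and enforces the nested-
    likelihood ordering up to Monte-Carlo noise.  The same seed is used for
    every model so composite likelihoods share a common genealogy stream.
    """
    fixed = fixed or {}
    model_kwargs = model_kwargs or {}
    results = {}
    for mid in model_ids:
        fx = {k: v for k, v in fixed.items()
              if k in MODELS[mid].param_names}
        m = SFSDemographyModel(observed, model=mid, fixed=fx, **model_kwargs)
        start = None
        if warm_nested:
            parents = [results[p] for p in _NESTED_PARENTS.get(mid, ())
                       if p in results]
            if parents:
                parent = max(parents, key=lambda r: r.llf)
                start = dict(parent.params)
                for name in MODELS[mid].param_names:
                    if name not in start and name in _RELEASED_FLOORS:
                        start[name] = _RELEASED_FLOORS[name]
                if mid in ("M6", "M7", "M8"):
                    start.setdefault("N_high_0", start["N_high"])
                    start.setdefault("N_low_0", start["N_low"])
                missing = [n for n in MODELS[mid].param_names
                           if n not in start and n not in fx]
                if missing:
                    start = None
        results[mid] = m.fit(seed=seed, start=start, **fit_kwargs)

    if warm_nested:
        _project_supermodel_optima(results, model_ids, seed)
    return [results[mid] for mid in model_ids]


def _project_supermodel_optima(results: dict, model_ids, seed: int) -> None:
    """Offer each submodel its supermodels' optima, projected.

    A supermodel explores a superset of the submodel's space (and, having
    been warm-started from the submodel, has effectively optimized longer),
    so its optimum with the released parameters reset to neutral values is a
    legal — often better — candidate point for the submodel.  Without this
    step a supermodel can outrank its submodel purely through extra
    optimization effort, which AIC would misread as evidence.
    """
    import dataclasses

    eval_seed = _stream_seed(seed, "fit_eval")
    for mid in model_ids:
        for parent in _NESTED_PARENTS.get(mid, ()):
            if parent not in results or mid not in results:
                continue
            child = results[mid]
            pres = results[parent]
            pmodel = pres.model
            proj = {k: v for k, v in child.params.items()
                    if k in MODELS[parent].param_names}
            proj.update(pmodel.fixed)
            missing = [n for n in MODELS[parent].param_names if n not in proj]
            if missing:
                continue
            eval_draws = pres.eval_draws or 20 * pmodel.n_draws
            ll = pmodel.loglike(proj, eval_seed, n_draws=eval_draws)
            if ll > pres.llf:
                results[parent] = dataclasses.replace(
                    pres, params=proj,
                    spec=pmodel.mspec.build_spec(proj, mu=pmodel.mu),
                    llf=ll,
                )


def compare_models(fits) -> pd.DataFrame:
    """AIC table over fits of the same observed SFS, best (lowest AIC) first."""
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to compare")
    n0 = fits[0].nobs
    for f in fits:
        if f.nobs != n0:
            raise ValueError("fits compare different observed SFS")
    rows = [
        {"model": f.model_id, "k": f.k, "loglik": f.llf, "aic": f.aic}
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table
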