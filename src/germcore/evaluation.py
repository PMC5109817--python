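"""Core-vs-entire evaluation: MD/CR/VD/VR, Shannon/evenness, hold-out markers.

Continuous (quantitative-trait) block, averaged over the m usable traits:

* ``MD% = (100/m) * sum_j |M_ej - M_cj| / |M_ej|`` — mean difference;
* ``VD% = (100/m) * sum_j |V_ej - V_cj| / V_ej`` — variance difference;
* ``CR% = (100/m) * sum_j R_cj / R_ej`` — coincidence rate of range;
* ``VR% = (100/m) * sum_j CV_cj / CV_ej`` — ratio of coefficients of
  variation;

where M/V/R/CV are the mean, sample variance (n-1), range (max-min) and
CV (= sd/mean * 100) of trait j in the entire (e) and core (c) sets.
These are relative-difference forms; a literature-compatible variant
counting significant t-tests is available via ``md_form="ttest"``.  A
core is judged representative when MD% < 20 and CR% > 80.

Categorical block: per-variable Shannon index I on class frequencies,
with I_max fixed at ln(class count *in the entire collection*) so that
core and entire evenness J' = I / I_max are directly comparable.  The
hold-out-marker validation instead uses each column's own observed
pattern count for I_max (per-column convention), reported side by side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

from .diversity import shannon_index
from .model import Collection, GenotypeMatrix
from .selection import CoreSet


@dataclass
class TraitEvaluation:
    name: str
    mean_entire: float
    mean_core: float
    var_entire: float
    var_core: float
    range_entire: float
    range_core: float
    cv_entire: float
    cv_core: float


@dataclass
class CategoricalEvaluation:
    I_core: float
    I_entire: float
    I_max: float
    J_core: float
    J_entire: float
    n_variables: int


@dataclass
class HoldoutValidation:
    marker_ids: list[str]
    n_patterns_entire: dict[str, int]
    n_patterns_core: dict[str, int]
    I_entire: dict[str, float]
    I_core: dict[str, float]
    I_max_entire: dict[str, float]
    I_max_core: dict[str, float]
    J_entire: dict[str, float]
    J_core: dict[str, float]

    def averages(self) -> dict[str, float]:
        def avg(d: dict[str, float]) -> float:
            return float(np.mean(list(d.values())))

        return {
            "I_entire": avg(self.I_entire),
            "I_core": avg(self.I_core),
            "I_max_entire": avg(self.I_max_entire),
            "I_max_core": avg(self.I_max_core),
            "J_entire": avg(self.J_entire),
            "J_core": avg(self.J_core),
        }


@dataclass
class EvaluationReport:
    strategy: str
    n_core: int
    n_entire: int
    pct_of_entire: float
    MD: float
    CR: float
    VD: float
    VR: float
    traits: list[TraitEvaluation]
    categorical: CategoricalEvaluation | None = None
    holdout: HoldoutValidation | None = None
    skipped_traits: list[str] = field(default_factory=list)

    @property
    def representative(self) -> bool:
        """MD% below 20 and CR% above 80."""
        return self.MD < 20.0 and self.CR > 80.0


def _trait_stats(values: list[float]) -> tuple[float, float, float, float]:
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    var = float(v.var(ddof=1))
    rng = float(v.max() - v.min())
    cv = float(np.sqrt(var) / mean * 100.0) if mean != 0 else float("nan")
    return mean, var, rng, cv


def evaluate_continuous(
    core_ids,
    collection: Collection,
    trait_names=None,
    md_form: str = "relative",
    alpha: float = 0.05,
):
    """MD/CR/VD/VR aggregates plus per-trait detail.

    Traits whose entire-collection mean, variance, range, or CV is zero
    (degenerate denominators) are skipped with a warning and excluded
    from the trait count m.  ``md_form="ttest"`` replaces MD%/VD% by the
    percentage of traits with a significant core-vs-entire Welch t-test
    (resp. Levene test) at ``alpha``.
    """
    if collection.phenotypes is None:
        raise ValueError("continuous evaluation requires phenotypes")
    p = collection.phenotypes
    names = trait_names or [t.name for t in p.quantitative_traits()]
    core_ids = list(core_ids)
    details: list[TraitEvaluation] = []
    skipped: list[str] = []
    md_terms, vd_terms, cr_terms, vr_terms = [], [], [], []
    sig_mean = sig_var = 0
    for name in names:
        entire_vals = [v for v in p.column(name) if v is not None]
        core_vals = [v for v in p.column(name, core_ids) if v is not None]
        if len(entire_vals) < 2 or len(core_vals) < 2:
            skipped.append(name)
            continue
        me, ve, re, cve = _trait_stats(entire_vals)
        mc, vc, rc, cvc = _trait_stats(core_vals)
        if me == 0 or ve == 0 or re == 0 or not np.isfinite(cve) or cve == 0:
            warnings.warn(f"trait {name!r}: zero denominator; skipped", stacklevel=2)
            skipped.append(name)
            continue
        details.append(TraitEvaluation(name, me, mc, ve, vc, re, rc, cve, cvc))
        md_terms.append(abs(me - mc) / abs(me))
        vd_terms.append(abs(ve - vc) / ve)
        cr_terms.append(rc / re)
        vr_terms.append(cvc / cve)
        if md_form == "ttest":
            t_p = _sps.ttest_ind(entire_vals, core_vals, equal_var=False).pvalue
            l_p = _sps.levene(entire_vals, core_vals).pvalue
            sig_mean += t_p < alpha
            sig_var += l_p < alpha
    m = len(md_terms)
    if m == 0:
        raise ValueError("no usable quantitative trait for evaluation")
    if md_form == "ttest":
        md = 100.0 * sig_mean / m
        vd = 100.0 * sig_var / m
    elif md_form == "relative":
        md = 100.0 * float(np.mean(md_terms))
        vd = 100.0 * float(np.mean(vd_terms))
    else:
        raise ValueError(f"unknown md_form {md_form!r}")
    cr = 100.0 * float(np.mean(cr_terms))
    vr = 100.0 * float(np.mean(vr_terms))
    return md, cr, vd, vr, details, skipped


def _class_freqs(values: list) -> dict[str, float]:
    obs = [v for v in values if v is not None]
    total = len(obs)
    out: dict[str, float] = {}
    for v in obs:
        out[v] = out.get(v, 0.0) + 1.0
    return {k: c / total for k, c in sorted(out.items())}


def evaluate_categorical(
    core_ids, collection: Collection, imax_convention: str = "fixed"
) -> CategoricalEvaluation:
    """Shannon I and evenness J' over categorical variables, core vs entire.

    Variables are the SNP markers (classes = observed genotype patterns)
    plus the qualitative traits.  With the default fixed convention,
    I_max for *both* sets is ln(entire-collection class count), making
    J' directly comparable; ``imax_convention="per-set"`` uses each
    set's own class count instead.
    """
    core_ids = list(core_ids)
    g = collection.genotypes
    variables: list[tuple[list, list]] = []  # (entire values, core values)
    core_idx = [g.accession_index(a) for a in core_ids]
    for j in range(g.n_markers):
        col = g.calls[:, j]
        entire = ["/".join(c) if c is not None else None for c in col]
        core = [entire[i] for i in core_idx]
        variables.append((entire, core))
    if collection.phenotypes is not None:
        p = collection.phenotypes
        for t in p.qualitative_traits():
            variables.append((p.column(t.name), p.column(t.name, core_ids)))
    I_e, I_c, Imax, J_e, J_c = [], [], [], [], []
    for entire, core in variables:
        fe = _class_freqs(entire)
        if len(fe) < 2:
            continue
        fc = _class_freqs(core)
        ie = shannon_index(fe.values())
        ic = shannon_index(fc.values()) if fc else 0.0
        imax_e = float(np.log(len(fe)))
        if imax_convention == "fixed":
            imax_c = imax_e
        elif imax_convention == "per-set":
            imax_c = float(np.log(len(fc))) if len(fc) >= 2 else float("nan")
        else:
            raise ValueError(f"unknown imax_convention {imax_convention!r}")
        I_e.append(ie)
        I_c.append(ic)
        Imax.append(imax_e)
        J_e.append(ie / imax_e)
        if np.isfinite(imax_c) and imax_c > 0:
            J_c.append(ic / imax_c)
    if not I_e:
        raise ValueError("no polymorphic categorical variable")
    return CategoricalEvaluation(
        I_core=float(np.mean(I_c)),
        I_entire=float(np.mean(I_e)),
        I_max=float(np.mean(Imax)),
        J_core=float(np.mean(J_c)),
        J_entire=float(np.mean(J_e)),
        n_variables=len(I_e),
    )


def validate_holdout(
    core_ids, holdouts: GenotypeMatrix, selection_marker_ids=None
) -> HoldoutValidation:
    """Hold-out multi-allelic marker validation (per-column I_max).

    Classes are the observed genotype patterns of each hold-out marker;
    I_max is ln(patterns observed in that column's own set), so core and
    entire each get their own ceiling.  Raises if a hold-out marker also
    appears among the selection markers.
    """
    if selection_marker_ids is not None:
        overlap = set(holdouts.marker_ids) & set(selection_marker_ids)
        if overlap:
            raise ValueError(f"hold-out markers overlap selection set: {sorted(overlap)}")
    core_ids = list(core_ids)
    core_idx = [holdouts.accession_index(a) for a in core_ids]
    np_e, np_c, I_e, I_c, Im_e, Im_c, J_e, J_c = {}, {}, {}, {}, {}, {}, {}, {}
    for j, mid in enumerate(holdouts.marker_ids):
        col = holdouts.calls[:, j]
        entire = ["/".join(c) if c is not None else None for c in col]
        core = [entire[i] for i in core_idx]
        fe, fc = _class_freqs(entire), _class_freqs(core)
        np_e[mid], np_c[mid] = len(fe), len(fc)
        I_e[mid] = shannon_index(fe.values()) if fe else 0.0
        I_c[mid] = shannon_index(fc.values()) if fc else 0.0
        Im_e[mid] = float(np.log(len(fe))) if fe else float("nan")
        Im_c[mid] = float(np.log(len(fc))) if fc else float("nan")
        J_e[mid] = I_e[mid] / Im_e[mid] if Im_e[mid] else float("nan")
        J_c[mid] = I_c[mid] / Im_c[mid] if Im_c[mid] else float("nan")
    return HoldoutValidation(
        list(holdouts.marker_ids), np_e, np_c, I_e, I_c, Im_e, Im_c, J_e, J_c
    )


def evaluate_core(
    core: CoreSet | list,
    collection: Collection,
    holdouts: GenotypeMatrix | None = None,
    md_form: str = "relative",
    imax_convention: str = "fixed",
) -> EvaluationReport:
    """Full evaluation of a core against the entire collection."""
    if isinstance(core, CoreSet):
        core_ids, strategy = core.selected_ids, core.strategy
    else:
        core_ids, strategy = list(core), "external"
    if not core_ids:
        raise ValueError("empty core set")
    md, cr, vd, vr, details, skipped = evaluate_continuous(
        core_ids, collection, md_form=md_form
    )
    categorical = evaluate_categorical(core_ids, collection, imax_convention)
    ho = None
    if holdouts is None and collection.holdout_genotypes is not None:
        holdouts = collection.holdout_genotypes
    if holdouts is not None:
        ho = validate_holdout(core_ids, holdouts, collection.genotypes.marker_ids)
    n_entire = collection.genotypes.n_accessions
    return EvaluationReport(
        strategy=strategy,
        n_core=len(core_ids),
        n_entire=n_entire,
        pct_of_entire=100.0 * len(core_ids) / n_entire,
        MD=md,
        CR=cr,
        VD=vd,
        VR=vr,
        traits=details,
        categorical=categorical,
        holdout=ho,
        skipped_traits=skipped,
    )
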