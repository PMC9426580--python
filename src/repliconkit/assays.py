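"""Colony-assay statistics, plasmid-stability estimation, prevalence dynamics,
plasmid-burden arithmetic, and in-silico PCR.

The statistics here deliberately stay exact and small-sample: colony screens
count tens to hundreds of colonies, so Clopper-Pearson intervals and exact
binomial tests are used throughout rather than normal approximations.  When no
loss event is observed at all, the rule-of-three bound 3/n is reported as the
95% upper limit instead of a degenerate zero-width interval.

Segregational stability is summarized by the per-generation loss rate
``lambda``: if a fraction R of colonies still carries the plasmid after G
generations of unselected growth, then under a constant per-division loss
probability R = (1 - lambda)^G, so lambda = 1 - R**(1/G).  The generation
count G is a required input — it depends on the cultivation protocol and is
not guessed here.

``project_prevalence`` links loss rate and fitness cost to the carrier
fraction over time: per generation the carrier fraction p follows

    p' = p(1-lambda) / [ p(1-lambda) + (1 - p(1-lambda))(1+s) ]

where s is the selective advantage of plasmid-free cells (s = 0: neutral).
Iterating this shows directly whether an observed prevalence can be explained
by instability and growth differences alone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta

__all__ = [
    "AssayCounts",
    "PrevalenceResult",
    "StabilityResult",
    "PrevalenceModel",
    "clopper_pearson",
    "rule_of_three",
    "prevalence_estimate",
    "stability_stats",
    "project_prevalence",
    "plasmid_burden",
    "PCRProduct",
    "insilico_pcr",
    "reverse_complement",
]


@dataclass
class AssayCounts:
    """Colony counts from a presence/absence screen."""

    n_tested: int
    n_positive: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.n_tested < 1:
            raise ValueError("n_tested must be >= 1")
        if not 0 <= self.n_positive <= self.n_tested:
            raise ValueError(
                f"n_positive ({self.n_positive}) must lie in [0, {self.n_tested}]"
            )

    @property
    def fraction(self) -> float:
        return self.n_positive / self.n_tested


@dataclass
class PrevalenceResult:
    point_pct: float
    ci_pct: tuple[float, float]
    rule_of_three_pct: float | None  # only set for 0/n or n/n outcomes


@dataclass
class StabilityResult:
    retention: float
    retention_ci: tuple[float, float]
    generations: int
    loss_rate: float
    loss_rate_ci: tuple[float, float]
    zero_loss_bound: float | None  # rule-of-three bound on retention loss, if R == 1


@dataclass
class PrevalenceModel:
    """Deterministic carrier-fraction dynamics parameters."""

    loss_rate: float  # per-generation segregational loss probability
    fitness_cost: float = 0.0  # selective advantage s of plasmid-FREE cells
    p0: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.loss_rate <= 1:
            raise ValueError("loss_rate must lie in [0, 1]")
        if not 0 <= self.p0 <= 1:
            raise ValueError("p0 must lie in [0, 1]")


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact (Clopper-Pearson) two-sided confidence interval for a proportion."""
    a = 1 - conf
    lo = beta.ppf(a / 2, k, n - k + 1) if k > 0 else 0.0
    hi = beta.ppf(1 - a / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)


def rule_of_three(n: int) -> float:
    """Upper 95% bound on a proportion when zero events were seen in n trials."""
    return 3.0 / n


def prevalence_estimate(assay: AssayCounts, conf: float = 0.95) -> PrevalenceResult:
    """Point estimate (in percent) and exact CI for a carriage screen."""
    point = 100.0 * assay.fraction
    lo, hi = clopper_pearson(assay.n_positive, assay.n_tested, conf)
    r3 = None
    if assay.n_positive in (0, assay.n_tested):
        r3 = 100.0 * rule_of_three(assay.n_tested)
    return PrevalenceResult(point_pct=point, ci_pct=(100 * lo, 100 * hi), rule_of_three_pct=r3)


def stability_stats(assay: AssayCounts, generations: int, conf: float = 0.95) -> StabilityResult:
    """Retention fraction and per-generation segregational loss rate.

    The loss-rate interval is the monotone transform lambda = 1 - R**(1/G) of
    the retention interval endpoints (order reversed: high retention means low
    loss).
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")
    r = assay.fraction
    r_lo, r_hi = clopper_pearson(assay.n_positive, assay.n_tested, conf)
    if r == 0:
        warnings.warn("no colony retained the plasmid; loss rate is 1 by convention")
        lam = 1.0
    else:
        lam = 1.0 - r ** (1.0 / generations)
    lam_ci = (1.0 - r_hi ** (1.0 / generations), 1.0 - r_lo ** (1.0 / generations) if r_lo > 0 else 1.0)
    zero_bound = rule_of_three(assay.n_tested) if r == 1.0 else None
    return StabilityResult(
        retention=r,
        retention_ci=(r_lo, r_hi),
        generations=generations,
        loss_rate=lam,
        loss_rate_ci=lam_ci,
        zero_loss_bound=zero_bound,
    )


def prevalence_step(p: float, loss_rate: float, fitness_cost: float) -> float:
    """One generation of the deterministic carrier-fraction recursion."""
    carriers = p * (1.0 - loss_rate)
    free = (1.0 - carriers) * (1.0 + fitness_cost)
    total = carriers + free
    return carriers / total if total > 0 else 0.0


def project_prevalence(model: PrevalenceModel, generations: int) -> np.ndarray:
    """Carrier-fraction trajectory p_0 ... p_G under loss and selection."""
    if generations < 0:
        raise ValueError("generations must be >= 0")
    traj = np.empty(generations + 1)
    traj[0] = model.p0
    for t in range(generations):
        traj[t + 1] = prevalence_step(traj[t], model.loss_rate, model.fitness_cost)
    return traj


def plasmid_burden(plasmid_bp: int, genome_bp: int, dna_energy_fraction: float) -> float:
    """Fraction of the cellular energy budget spent replicating a plasmid.

    Simply (plasmid size / genome size) x (fraction of the energy budget that
    DNA synthesis consumes).  Returned as a fraction, not percent.
    """
    if plasmid_bp < 0 or genome_bp <= 0:
        raise ValueError("sizes must be positive")
    if plasmid_bp > genome_bp:
        raise ValueError("plasmid cannot exceed the genome it belongs to")
    if not 0 <= dna_energy_fraction <= 1:
        raise ValueError("dna_energy_fraction must lie in [0, 1]")
    return (plasmid_bp / genome_bp) * dna_energy_fraction


# ---------------------------------------------------------------------------
# in-silico PCR

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class PCRProduct:
    start: int  # 0-based start of the forward-primer site on the template
    end: int  # 0-based end (exclusive) of the reverse-primer site; may exceed
    # template length for circular products spanning the origin
    length: int


def _match_positions(template: str, probe: str, max_mismatch: int) -> list[int]:
    """Start positions where probe matches template with <= max_mismatch
    substitutions (no indels)."""
    hits = []
    m = len(probe)
    for i in range(len(template) - m + 1):
        mism = 0
        for a, b in zip(template[i : i + m], probe):
            if a != b:
                mism += 1
                if mism > max_mismatch:
                    break
        else:
            hits.append(i)
    return hits


def insilico_pcr(
    template: str,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch: int = 0,
    circular: bool = False,
    max_product_length: int = 10000,
) -> list[PCRProduct]:
    """Predict PCR products of a primer pair on a template.

    The forward primer is matched on the plus strand; the reverse primer
    anneals to the plus strand as its reverse complement, downstream of the
    forward site.  Product length runs from the start of the forward site to
    the end of the reverse site, primers included.  Circular templates are
    scanned across the origin; positions are reported modulo the template
    length with ``end`` allowed to wrap past it.
    """
    template = template.upper()
    fwd = fwd_primer.upper()
    rev_rc = reverse_complement(rev_primer)
    if min(len(fwd), len(rev_primer)) < 15:
        raise ValueError("primers must be at least 15 nt")
    n = len(template)
    search = template + template[: min(max_product_length, n)] if circular else template
    fwd_sites = [i for i in _match_positions(search, fwd, max_mismatch) if i < n]
    rev_sites = _match_positions(search, rev_rc, max_mismatch)
    products = []
    seen = set()
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev_rc)
            length = end - f
            if length < len(fwd) + len(rev_rc) or length > max_product_length:
                continue
            key = (f % n, end % n if circular else end)
            if key in seen:
                continue
            seen.add(key)
            products.append(PCRProduct(start=f, end=end, length=length))
    return sorted(products, key=lambda p: (p.start, p.length))
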