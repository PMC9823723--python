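"""Likelihood-ratio verification of pedigree hypotheses.

For each pedigree claim (child with an assumed mother and/or father) the
LOD score is the summed per-locus natural-log ratio of the likelihood of
the child's genotype given the named parents to its likelihood given
unrelated Hardy-Weinberg parents.  Genotyping error is modeled in the
classic CERVUS way: each observed single-locus genotype is, independently
and with probability ``error_rate``, a random HWE genotype instead of the
true one — so Mendelian exclusions are penalized, not fatal, when the
error rate is positive.

Confidence is calibrated by simulation: offspring of HWE parents are
generated, degraded with the configured missingness and mistyping, scored
against a candidate set containing the true parent with probability
``prop_parents_sampled``, and the LOD thresholds are set so that
assignments exceeding them are correct in at least 95% (strict) / 80%
(relaxed) of simulations — mirroring the standard CERVUS protocol.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .core import PedigreeHypothesis, SSRGenotype
from .diversity_stats import AlleleFrequencyTable

log = logging.getLogger(__name__)


class Mode(enum.Enum):
    TRIO = "trio"
    MOTHER_PAIR = "mother_pair"
    FATHER_PAIR = "father_pair"


class Verdict(enum.Enum):
    STRICT_95 = "*"
    RELAXED_80 = "+"
    BELOW = "-"
    UNEVALUATED = "unevaluated"


@dataclass(frozen=True)
class ParentageConfig:
    """Simulation and scoring parameters (CERVUS-style).

    Defaults follow routine practice for verifying genebank pedigrees:
    100,000 simulated progeny, 95% of candidate parents sampled, 90% of
    loci typed, 10% mistyping, at least 13 typed loci, relaxed/strict
    confidence at 80%/95%, and candidate-set sizes of 31 (parent pairs),
    18 (mothers) and 7 (fathers).
    """

    n_simulated_progeny: int = 100_000
    prop_parents_sampled: float = 0.95
    prop_loci_typed: float = 0.9
    error_rate: float = 0.1
    min_typed_loci: int = 13
    relaxed_confidence: float = 0.80
    strict_confidence: float = 0.95
    n_candidates: Mapping[Mode, int] = field(
        default_factory=lambda: {Mode.TRIO: 31, Mode.MOTHER_PAIR: 18, Mode.FATHER_PAIR: 7}
    )
    statistic: str = "lod"  # "lod" or "delta" (best minus second best)

    def __post_init__(self) -> None:
        for name in ("prop_parents_sampled", "prop_loci_typed"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.statistic not in ("lod", "delta"):
            raise ValueError("statistic must be 'lod' or 'delta'")


@dataclass(frozen=True)
class LocusLikelihood:
    locus: str
    numerator: float  # L(child | named parents), error model applied
    baseline: float  # L(child | unrelated HWE parents)
    mendelian_exclusion: bool  # incompatible ignoring the error model


@dataclass(frozen=True)
class ParentageResult:
    hypothesis: PedigreeHypothesis
    mode: Optional[Mode]
    lod: float
    verdict: Verdict
    loci_compared: int
    mismatching_loci: int
    note: str = ""


@dataclass(frozen=True)
class CalibratedThresholds:
    mode: Mode
    strict_lod: float
    relaxed_lod: float
    assignment_rate_strict: float  # fraction of simulations above strict
    n_simulations: int


# ---------------------------------------------------------------------------
# Single-locus transition probabilities (scalar path, used for real data)


def _freq(lf, allele: int) -> float:
    """Allele frequency with a small floor for alleles unseen in the
    reference table (e.g. introduced by typing error)."""
    floor = 0.5 / lf.n_copies
    return max(lf.freqs.get(allele, 0.0), floor)


def _t0(lf, child: tuple[int, int]) -> float:
    a, b = child
    pa, pb = _freq(lf, a), _freq(lf, b)
    return pa * pb * (2.0 if a != b else 1.0)


def _trans_from(parent: tuple[int, int], allele: int) -> float:
    return 0.5 * ((allele == parent[0]) + (allele == parent[1]))


def _t1(lf, child: tuple[int, int], parent: tuple[int, int]) -> float:
    a, b = child
    pa, pb = _freq(lf, a), _freq(lf, b)
    if a == b:
        return _trans_from(parent, a) * pa
    return _trans_from(parent, a) * pb + _trans_from(parent, b) * pa


def _t2(
    lf, child: tuple[int, int], mother: tuple[int, int], father: tuple[int, int]
) -> float:
    a, b = child
    if a == b:
        return _trans_from(mother, a) * _trans_from(father, a)
    return _trans_from(mother, a) * _trans_from(father, b) + _trans_from(
        mother, b
    ) * _trans_from(father, a)


def genotype_likelihood(
    child: SSRGenotype,
    mother: Optional[SSRGenotype],
    father: Optional[SSRGenotype],
    freqs: AlleleFrequencyTable,
    error_rate: float,
) -> list[LocusLikelihood]:
    """Per-locus likelihoods of the child genotype given the named parents.

    Loci missing in the child or in all named parents are skipped.  With
    ``error_rate`` e, each observed genotype is an HWE draw with
    probability e, marginalized independently for child and each parent.
    """
    if mother is None and father is None:
        raise ValueError("at least one parent genotype is required")
    e = error_rate
    out: list[LocusLikelihood] = []
    for locus in freqs.loci:
        c = child.alleles.get(locus)
        if c is None:
            continue
        gm = mother.alleles.get(locus) if mother is not None else None
        gf = father.alleles.get(locus) if father is not None else None
        if gm is None and gf is None:
            continue
        lf = freqs[locus]
        t0 = _t0(lf, c)
        if gm is not None and gf is not None:
            clean = _t2(lf, c, gm, gf)
            x = (
                (1 - e) ** 2 * clean
                + e * (1 - e) * _t1(lf, c, gf)
                + (1 - e) * e * _t1(lf, c, gm)
                + e**2 * t0
            )
        else:
            parent = gm if gm is not None else gf
            clean = _t1(lf, c, parent)  # type: ignore[arg-type]
            x = (1 - e) * clean + e * t0
        num = (1 - e) * x + e * t0
        out.append(LocusLikelihood(locus, num, t0, mendelian_exclusion=clean == 0.0))
    return out


def lod(
    hypothesis: PedigreeHypothesis,
    child: SSRGenotype,
    mother: Optional[SSRGenotype],
    father: Optional[SSRGenotype],
    freqs: AlleleFrequencyTable,
    config: ParentageConfig,
) -> ParentageResult:
    """LOD of a single pedigree hypothesis (verdict left UNEVALUATED)."""
    if mother is not None and father is not None:
        mode = Mode.TRIO
    elif mother is not None:
        mode = Mode.MOTHER_PAIR
    else:
        mode = Mode.FATHER_PAIR
    note = ""
    if any(
        parent is not None and parent.key() == child.key()
        for parent in (mother, father)
    ):
        note = "consanguinity warning: parent genotype identical to child"
        log.warning("%s: %s", hypothesis.child, note)
    liks = genotype_likelihood(child, mother, father, freqs, config.error_rate)
    if len(liks) < config.min_typed_loci:
        return ParentageResult(
            hypothesis,
            mode,
            float("nan"),
            Verdict.UNEVALUATED,
            len(liks),
            0,
            note="fewer than min_typed_loci usable loci",
        )
    score = 0.0
    mismatches = 0
    for ll in liks:
        mismatches += ll.mendelian_exclusion
        score += math.log(ll.numerator / ll.baseline) if ll.numerator > 0 else -math.inf
    return ParentageResult(
        hypothesis, mode, score, Verdict.UNEVALUATED, len(liks), mismatches, note
    )


# ---------------------------------------------------------------------------
# Vectorized simulation engine (threshold calibration)


def _locus_setup(freqs: AlleleFrequencyTable) -> list[np.ndarray]:
    return [freqs[l].freq_array for l in freqs.loci]


def _draw_genotypes(rng, p: np.ndarray, shape) -> tuple[np.ndarray, np.ndarray]:
    a = rng.choice(len(p), size=shape, p=p)
    b = rng.choice(len(p), size=shape, p=p)
    return a, b


def _mendelian_child(rng, M, F):
    """Child allele indices from parent genotype arrays (each (n, 2))."""
    n = M[0].shape[0]
    pick_m = rng.integers(2, size=n)
    pick_f = rng.integers(2, size=n)
    a = np.where(pick_m == 0, M[0], M[1])
    b = np.where(pick_f == 0, F[0], F[1])
    return a, b


def _observe(rng, pair, p, typed_p, err_p):
    """Apply missingness and HWE-replacement mistyping to genotype arrays."""
    a, b = pair
    typed = rng.random(a.shape) < typed_p
    err = rng.random(a.shape) < err_p
    ra, rb = _draw_genotypes(rng, p, a.shape)
    a = np.where(err, ra, a)
    b = np.where(err, rb, b)
    return a, b, typed


def _pair_lod_terms(p, ca, cb, ma, mb, e):
    """ln-likelihood-ratio terms for single-parent hypotheses (vectorized).

    ``ca, cb``: child alleles, broadcastable against the candidate parent
    arrays ``ma, mb``.
    """
    pa, pb = p[ca], p[cb]
    het = ca != cb
    t0 = pa * pb * np.where(het, 2.0, 1.0)
    trans_a = 0.5 * ((ca == ma).astype(float) + (ca == mb).astype(float))
    trans_b = 0.5 * ((cb == ma).astype(float) + (cb == mb).astype(float))
    t1 = np.where(het, trans_a * pb + trans_b * pa, trans_a * pa)
    num = (1 - e) * ((1 - e) * t1 + e * t0) + e * t0
    return np.log(num / t0)


def _trio_lod_terms(p, ca, cb, ma, mb, fa, fb, e):
    pa, pb = p[ca], p[cb]
    het = ca != cb
    t0 = pa * pb * np.where(het, 2.0, 1.0)
    tma = 0.5 * ((ca == ma).astype(float) + (ca == mb).astype(float))
    tmb = 0.5 * ((cb == ma).astype(float) + (cb == mb).astype(float))
    tfa = 0.5 * ((ca == fa).astype(float) + (ca == fb).astype(float))
    tfb = 0.5 * ((cb == fa).astype(float) + (cb == fb).astype(float))
    t2 = np.where(het, tma * tfb + tmb * tfa, tma * tfa)
    t1m = np.where(het, tma * pb + tmb * pa, tma * pa)
    t1f = np.where(het, tfa * pb + tfb * pa, tfa * pa)
    x = (1 - e) ** 2 * t2 + e * (1 - e) * t1f + (1 - e) * e * t1m + e**2 * t0
    num = (1 - e) * x + e * t0
    return np.log(num / t0)


def _threshold_from_scores(stats, correct, level, z=3.0):
    """Smallest statistic t with precision(correct | stat >= t) >= level.

    The precision of the simulated assignments above each candidate
    threshold is assessed by its one-sided Wilson lower confidence bound
    (z = 3), so the confidence statement is conservative with respect to
    simulation noise and transfers to fresh data instead of holding only
    in-sample.
    """
    order = np.argsort(-stats, kind="stable")
    s = stats[order]
    c = correct[order].astype(float)
    n = np.arange(1, len(c) + 1)
    phat = np.cumsum(c) / n
    denom = 1 + z**2 / n
    center = phat + z**2 / (2 * n)
    spread = z * np.sqrt(phat * (1 - phat) / n + z**2 / (4 * n**2))
    lower = (center - spread) / denom
    ok = np.where(lower >= level)[0]
    if len(ok) == 0:
        return float("inf")
    return float(s[ok[-1]])


def simulate_assignments(
    freqs: AlleleFrequencyTable,
    config: ParentageConfig,
    mode: Mode,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate most-likely-candidate assignments for one analysis mode.

    ``n_simulated_progeny`` offspring of random HWE parents are degraded
    with the configured missingness and mistyping and scored against a
    candidate set whose slot 0 holds the true parent (pair) with
    probability ``prop_parents_sampled``.  Returns the assignment
    statistic (LOD or delta) of the most likely candidate per simulation,
    and whether that candidate was the true parent.
    """
    ps = _locus_setup(freqs)
    if all(len(p) < 2 for p in ps):
        raise ValueError("cannot simulate on a monomorphic panel")
    mode_stream = {Mode.TRIO: 0, Mode.MOTHER_PAIR: 1, Mode.FATHER_PAIR: 2}[mode]
    rng = np.random.default_rng(np.random.SeedSequence((seed, mode_stream)))
    n = config.n_simulated_progeny
    n_cand = config.n_candidates[mode]
    e = config.error_rate

    def cand_side(p, true_pair, sampled):
        """Candidate genotypes (n, n_cand); slot 0 = true parent when sampled."""
        ga, gb = _draw_genotypes(rng, p, (n, n_cand))
        ga[:, 0] = np.where(sampled, true_pair[0], ga[:, 0])
        gb[:, 0] = np.where(sampled, true_pair[1], gb[:, 0])
        return _observe(rng, (ga, gb), p, config.prop_loci_typed, e)

    if mode is Mode.TRIO:
        # candidate mother x father pairs, each side sampled independently;
        # half-right pairs are counted incorrect, which is what pushes the
        # strict threshold above single-wrong-parent hypotheses
        m_sampled = rng.random(n) < config.prop_parents_sampled
        f_sampled = rng.random(n) < config.prop_parents_sampled
        n_pairs = n_cand * n_cand
        lod_sum = np.zeros((n, n_pairs))
        usable = np.zeros((n, n_pairs), dtype=np.int16)
        chunk = max(1, min(n, 2_000_000 // n_pairs + 1))
        for p in ps:
            if len(p) < 2:
                continue
            M = _draw_genotypes(rng, p, n)
            F = _draw_genotypes(rng, p, n)
            ca, cb = _mendelian_child(rng, M, F)
            ca, cb, ctyped = _observe(rng, (ca, cb), p, config.prop_loci_typed, e)
            ma, mb, mtyped = cand_side(p, M, m_sampled)
            fa, fb, ftyped = cand_side(p, F, f_sampled)
            for s in range(0, n, chunk):
                sl = slice(s, min(n, s + chunk))
                cA, cB = ca[sl, None, None], cb[sl, None, None]
                het = cA != cB
                pa, pb = p[cA], p[cB]
                t0 = pa * pb * np.where(het, 2.0, 1.0)
                half = lambda x, g1, g2: 0.5 * (
                    (x == g1).astype(float) + (x == g2).astype(float)
                )
                tma = half(cA, ma[sl, :, None], mb[sl, :, None])
                tmb = half(cB, ma[sl, :, None], mb[sl, :, None])
                tfa = half(cA, fa[sl, None, :], fb[sl, None, :])
                tfb = half(cB, fa[sl, None, :], fb[sl, None, :])
                t2 = np.where(het, tma * tfb + tmb * tfa, tma * tfa)
                t1m = np.where(het, tma * pb + tmb * pa, tma * pa)
                t1f = np.where(het, tfa * pb + tfb * pa, tfa * pa)
                x = (1 - e) ** 2 * t2 + e * (1 - e) * t1f + (1 - e) * e * t1m + e**2 * t0
                trio = np.log(((1 - e) * x + e * t0) / t0)
                pm = np.log(((1 - e) * ((1 - e) * t1m + e * t0) + e * t0) / t0)
                pf = np.log(((1 - e) * ((1 - e) * t1f + e * t0) + e * t0) / t0)
                mt = mtyped[sl, :, None]
                ft = ftyped[sl, None, :]
                terms = np.where(mt & ft, trio, 0.0)
                terms = np.where(mt & ~ft, pm, terms)
                terms = np.where(ft & ~mt, pf, terms)
                use = ctyped[sl, None, None] & (mt | ft)
                lod_sum[sl] += np.where(use, terms, 0.0).reshape(sl.stop - sl.start, n_pairs)
                usable[sl] += use.reshape(sl.stop - sl.start, n_pairs)
        sampled_ok = m_sampled & f_sampled
    else:
        sampled_ok = rng.random(n) < config.prop_parents_sampled
        lod_sum = np.zeros((n, n_cand))
        usable = np.zeros((n, n_cand), dtype=np.int16)
        for p in ps:
            if len(p) < 2:
                continue
            M = _draw_genotypes(rng, p, n)
            F = _draw_genotypes(rng, p, n)
            ca, cb = _mendelian_child(rng, M, F)
            ca, cb, ctyped = _observe(rng, (ca, cb), p, config.prop_loci_typed, e)
            true_pair = M if mode is Mode.MOTHER_PAIR else F
            ga, gb, ptyped = cand_side(p, true_pair, sampled_ok)
            terms = _pair_lod_terms(p, ca[:, None], cb[:, None], ga, gb, e)
            use = ctyped[:, None] & ptyped
            lod_sum += np.where(use, terms, 0.0)
            usable += use

    valid = usable >= config.min_typed_loci
    lod_eval = np.where(valid, lod_sum, -np.inf)
    best_ix = np.argmax(lod_eval, axis=1)
    best = lod_eval[np.arange(n), best_ix]
    if config.statistic == "delta":
        part = np.partition(lod_eval, -2, axis=1)
        second = part[:, -2]
        stats = best - np.where(np.isfinite(second), second, 0.0)
    else:
        stats = best
    has_assignment = np.isfinite(best)
    correct = (best_ix == 0) & sampled_ok & has_assignment
    return stats[has_assignment], correct[has_assignment]


def assignment_precision(
    freqs: AlleleFrequencyTable,
    config: ParentageConfig,
    thresholds: "dict[Mode, CalibratedThresholds]",
    seed: int,
) -> dict[Mode, float]:
    """Out-of-sample check: fraction of correct assignments among fresh
    simulated assignments scoring at or above the strict threshold."""
    out = {}
    for mode, th in thresholds.items():
        stats, correct = simulate_assignments(freqs, config, mode, seed)
        above = stats >= th.strict_lod
        out[mode] = float(correct[above].mean()) if above.any() else float("nan")
    return out


def calibrate_thresholds(
    freqs: AlleleFrequencyTable,
    config: ParentageConfig,
    seed: int,
    modes: Sequence[Mode] = (Mode.TRIO, Mode.MOTHER_PAIR, Mode.FATHER_PAIR),
) -> dict[Mode, CalibratedThresholds]:
    """Simulate assignments and derive strict/relaxed LOD thresholds.

    For each mode, the thresholds are the smallest statistic values at
    which the simulated assignment precision reaches the strict / relaxed
    confidence levels.
    """
    out: dict[Mode, CalibratedThresholds] = {}
    for mode in modes:
        stats, correct = simulate_assignments(freqs, config, mode, seed)

        strict = _threshold_from_scores(stats, correct, config.strict_confidence)
        relaxed = _threshold_from_scores(stats, correct, config.relaxed_confidence)
        relaxed = min(relaxed, strict)
        out[mode] = CalibratedThresholds(
            mode=mode,
            strict_lod=strict,
            relaxed_lod=relaxed,
            assignment_rate_strict=float(np.mean(stats >= strict)) if len(stats) else 0.0,
            n_simulations=int(len(stats)),
        )
    return out


def verify_pedigrees(
    hypotheses: Sequence[PedigreeHypothesis],
    genotypes: Mapping[str, SSRGenotype],
    freqs: AlleleFrequencyTable,
    config: ParentageConfig,
    seed: int,
    thresholds: Optional[dict[Mode, CalibratedThresholds]] = None,
) -> list[ParentageResult]:
    """Label every pedigree hypothesis '*' (strict), '+' (relaxed) or '-'.

    ``genotypes`` maps cultivar names to harmonized fingerprints; a
    hypothesis whose child has no genotype is emitted UNEVALUATED.  The
    mode (trio vs single-parent pair) follows which parents are genotyped.
    """
    needed = set()
    for h in hypotheses:
        gm = genotypes.get(h.assumed_mother) if h.assumed_mother else None
        gf = genotypes.get(h.assumed_father) if h.assumed_father else None
        if gm is not None and gf is not None:
            needed.add(Mode.TRIO)
        elif gm is not None:
            needed.add(Mode.MOTHER_PAIR)
        elif gf is not None:
            needed.add(Mode.FATHER_PAIR)
    if thresholds is None:
        thresholds = calibrate_thresholds(freqs, config, seed, modes=sorted(needed, key=lambda m: m.value))

    results = []
    for h in hypotheses:
        child = genotypes.get(h.child)
        gm = genotypes.get(h.assumed_mother) if h.assumed_mother else None
        gf = genotypes.get(h.assumed_father) if h.assumed_father else None
        if child is None or (gm is None and gf is None):
            results.append(
                ParentageResult(
                    h,
                    None,
                    float("nan"),
                    Verdict.UNEVALUATED,
                    0,
                    0,
                    note="child or both parents lack genotypes",
                )
            )
            continue
        res = lod(h, child, gm, gf, freqs, config)
        if res.verdict is Verdict.UNEVALUATED and math.isnan(res.lod):
            results.append(res)
            continue
        th = thresholds[res.mode]
        if res.lod >= th.strict_lod:
            verdict = Verdict.STRICT_95
        elif res.lod >= th.relaxed_lod:
            verdict = Verdict.RELAXED_80
        else:
            verdict = Verdict.BELOW
        results.append(replace(res, verdict=verdict))
    return results
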