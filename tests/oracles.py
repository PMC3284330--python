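"""Independent brute-force oracles shared across test modules.

These deliberately reimplement the quantities under test with plain loops
and explicit formulas, staying independent of the package's vectorized
code paths.
"""

import math

import numpy as np

from gofuse.pair_features import canonical_pair


def brute_force_pr(scores, positives):
    """O(n^2) threshold sweep with the pessimistic (>= threshold) tie rule."""
    thresholds = sorted(set(scores.values()), reverse=True)
    prec, rec = [], []
    for tau in thresholds:
        called = [g for g, s in scores.items() if s >= tau]
        tp = sum(1 for g in called if g in positives)
        prec.append(tp / len(called))
        rec.append(tp / len(positives & set(scores)))
    ap = 0.0
    for g in positives & set(scores):
        tau = scores[g]
        ap += prec[thresholds.index(tau)]
    ap /= len(positives & set(scores))
    return thresholds, prec, rec, ap


def density_eval(sample, x):
    """Augmented-KDE density at x, written out long-hand: Silverman-rule
    Gaussian kernels mixed with a Uniform[0,1] component of weight
    1/(n+1), floored at 1e-12."""
    n = len(sample)
    if n > 1:
        mean = sum(sample) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in sample) / (n - 1))
    else:
        sd = 0.0
    q25, q75 = (np.percentile(sorted(sample), [25, 75]) if n > 1 else (0.0, 0.0))
    spread = min(sd, (q75 - q25) / 1.34) if (q75 - q25) > 1e-12 else sd
    h = 0.05 if spread <= 1e-12 else 0.9 * spread * n ** (-0.2)
    kde = sum(
        math.exp(-0.5 * ((x - s) / h) ** 2) for s in sample
    ) / (n * h * math.sqrt(2 * math.pi))
    return max(n / (n + 1) * kde + 1 / (n + 1), 1e-12)


def brute_force_llr_transfer(g, core, core_sample, noncore_sample, weights):
    """Straight-line annotation-transfer LLR for one candidate gene."""
    llr = 0.0
    for c in sorted(core):
        w = weights[canonical_pair(g, c)]
        llr += math.log(density_eval(core_sample, w)) - math.log(
            density_eval(noncore_sample, w)
        )
    return llr


def brute_force_loo(t, fln, ann, training, pooled_terms=None, pooled_max=10):
    """Straight-line leave-one-out GBA scoring: rebuild both densities per
    held-out gene with explicit loops over the surviving pairs."""
    C = ann.genes_for(t) & training
    out = {}
    for g in sorted(training):
        Cg = sorted(C - {g})
        if not Cg:
            out[g] = 0.0
            continue
        if len(C) <= pooled_max or len(Cg) < 2:
            terms = pooled_terms if pooled_terms is not None else [t]
            core_w, noncore_w = [], []
            for tt in terms:
                Ct = sorted((ann.genes_for(tt) & training) - {g})
                Nt = sorted(training - (ann.genes_for(tt) & training) - {g})
                for i in range(len(Ct)):
                    for j in range(i + 1, len(Ct)):
                        core_w.append(fln.weights[canonical_pair(Ct[i], Ct[j])])
                for u in Nt:
                    for c in Ct:
                        noncore_w.append(fln.weights[canonical_pair(u, c)])
        else:
            noncore = sorted(training - C - {g})
            core_w = [
                fln.weights[canonical_pair(Cg[i], Cg[j])]
                for i in range(len(Cg)) for j in range(i + 1, len(Cg))
            ]
            noncore_w = [
                fln.weights[canonical_pair(u, c)] for u in noncore for c in Cg
            ]
        out[g] = brute_force_llr_transfer(g, Cg, core_w, noncore_w, fln.weights)
    return out
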