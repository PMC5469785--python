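"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorised log-space code paths:
exact rational arithmetic for the removal recursion, and explicit truncated
summation over the latent abundance for the marginal likelihood and the
latent-N conditional.
"""

from fractions import Fraction

import numpy as np
from scipy import stats


def enumerate_fates(c_seq, d_seq):
    """Exact per-survey fate probabilities for a single individual.

    Walks the death-then-capture event tree survey by survey with exact
    ``Fraction`` arithmetic.  Returns (pi, delta, phi_final) where ``pi[t]``
    is the probability of first removal by capture at survey ``t`` and
    ``delta[t]`` by death.
    """
    alive = Fraction(1)
    pi, delta = [], []
    for c, d in zip(c_seq, d_seq):
        c, d = Fraction(c), Fraction(d)
        delta.append(alive * d)
        pi.append(alive * (1 - d) * c)
        alive = alive * (1 - d) * (1 - c)
    return pi, delta, alive


def negbin_pmf(k, mu, sigma):
    """NegBin(mean mu, size sigma) pmf, scipy parameterisation."""
    p = sigma / (sigma + mu)
    return stats.nbinom.pmf(k, sigma, p)


def marginal_loglik_bruteforce(c, d, mu, sigma, y, n_max=4000):
    """Truncated-sum marginal log likelihood.

    ``c``/``d`` are (T, P) effective probability matrices and ``y`` the
    (T, P) counts.  For each point the latent abundance is summed out
    explicitly: ``sum_N Bin(n | q, N) NegBin(N | mu, sigma)`` with the
    multinomial factor for the within-survey split.
    """
    from eradimix import removal_probabilities

    rp = removal_probabilities(c, d)
    total = 0.0
    for i in range(y.shape[1]):
        n_i = int(y[:, i].sum())
        q = float(rp.capture_total[i])
        Ns = np.arange(n_i, n_max + 1)
        marg = float(
            (stats.binom.pmf(n_i, Ns, q) * negbin_pmf(Ns, mu, sigma)).sum()
        )
        if n_i > 0:
            cell = rp.pi_prime[:, i] / q
            mult = float(stats.multinomial.pmf(y[:, i], n_i, cell))
        else:
            mult = 1.0
        total += np.log(mult * marg)
    return total


def latent_N_pmf_bruteforce(n, q, mu, sigma, n_max=6000):
    """Normalised conditional pmf of N on ``n .. n_max`` given ``n`` removals."""
    Ns = np.arange(n, n_max + 1)
    w = stats.binom.pmf(n, Ns, q) * negbin_pmf(Ns, mu, sigma)
    return Ns, w / w.sum()


def nec_scan(presence, Cs, Ce):
    """Exhaustive search for the cheapest declaration month (first minimiser)."""
    best_m, best_v = None, None
    for m, pres in enumerate(presence, start=1):
        v = (m - 1) * Cs + pres * Ce
        if best_v is None or v < best_v:
            best_m, best_v = m, v
    return best_m, best_v
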