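"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's pruning/bitmask code paths: tree
likelihoods are computed by exhaustive enumeration over internal-node state
assignments, parsimony by exhaustive minimisation, and fixation
probabilities by forward population simulation.
"""

from itertools import product

import numpy as np
from scipy.linalg import expm


def enumerate_loglik(tree, pattern, q, root_freq):
    """Site log-likelihood by summing over all internal-node states."""
    internals = [n for n in tree.postorder if not tree.is_leaf(n)]
    p = {int(n): expm(q * float(tree.lengths[n])) for n in tree.branch_nodes}
    total = 0.0
    for states in product(range(4), repeat=len(internals)):
        assign = dict(zip(internals, states))
        term = root_freq[assign[tree.root]]
        for n in tree.postorder[:-1]:
            parent_state = assign[tree.parent[n]]
            if tree.is_leaf(n):
                obs = pattern[n]
                if obs == 4:  # missing: sum over leaf states = row sum = 1
                    term *= 1.0
                else:
                    term *= p[int(n)][parent_state, obs]
            else:
                term *= p[int(n)][parent_state, assign[n]]
        total += term
    return np.log(total)


def enumerate_parsimony(tree, pattern):
    """Minimum state changes over all internal-node labelings."""
    internals = [n for n in tree.postorder if not tree.is_leaf(n)]
    leaves = [n for n in tree.postorder if tree.is_leaf(n)]
    best = np.inf
    leaf_sets = {
        int(n): (range(4) if pattern[n] == 4 else [int(pattern[n])]) for n in leaves
    }
    for states in product(range(4), repeat=len(internals)):
        assign = dict(zip(internals, states))
        for leaf_states in product(*[leaf_sets[int(n)] for n in leaves]):
            assign.update(dict(zip([int(n) for n in leaves], leaf_states)))
            changes = 0
            for n in tree.postorder[:-1]:
                if assign[int(n)] != assign[int(tree.parent[n])]:
                    changes += 1
            best = min(best, changes)
    return int(best)


def wright_fisher_fixation(s, ne, n_intro, seed):
    """Fraction of new mutants that fix in a diploid Wright-Fisher
    population of Ne individuals (2Ne gene copies).

    The model's fitness convention is multiplicative across loci with
    semidominance, so each mutant copy carries relative fitness e^(s/2)
    where e^(-s) is the resident/mutant (homozygote) fitness ratio.
    """
    rng = np.random.default_rng(seed)
    n = int(2 * ne)
    w = np.exp(s / 2.0)
    counts = np.ones(n_intro, dtype=np.int64)
    active = np.arange(n_intro)
    fixed = 0
    while active.size:
        p = counts[active] / n
        p_sel = p * w / (p * w + (1.0 - p))
        counts[active] = rng.binomial(n, p_sel)
        done = (counts[active] == 0) | (counts[active] == n)
        fixed += int((counts[active[done]] == n).sum())
        active = active[~done]
    return fixed / n_intro
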