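"""Forward Markov-chain imputation of missing haploid-coded genotypes.

Post-QC inbred genotypes live on the two-state space {0, 2} (major/minor
homozygote).  Along each chromosome the calls of one line are modelled as a
first-order Markov chain whose transition table between adjacent sites is
estimated from the lines observed at both sites (with pseudocount
smoothing).  Imputation is a deterministic greedy forward pass: a missing
call is filled with the argmax of the transition row conditioned on the most
recent observed-or-imputed state, or with the site-marginal argmax when no
prior state exists on that chromosome.  Ties break toward the major allele.

The masked-data protocol in :func:`estimate_accuracy` hides a fraction of
observed calls, refits the model on the masked matrix, imputes, and scores
the hidden cells against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix import MAJOR, MINOR, MISSING, GenotypeMatrix

_STATE_OF = {MAJOR: 0, MINOR: 1}
_CALL_OF = np.array([MAJOR, MINOR], dtype=np.int8)


class ImputeError(ValueError):
    pass


@dataclass
class MarkovModel:
    """Adjacent-site transition tables and site marginals, per chromosome.

    ``transitions[chrom]`` has shape ``(n_sites-1, 2, 2)`` with rows
    normalised to 1 (``None`` for chromosomes with < 2 sites);
    ``marginals[chrom]`` has shape ``(n_sites, 2)``.
    """

    site_index: dict  # chrom -> (chrom key tuple list) for identity checks
    transitions: dict
    marginals: dict
    pseudocount: float = 0.5

    def check_sites(self, gm: GenotypeMatrix) -> None:
        for chrom, sl in gm.chrom_slices().items():
            keys = list(zip(gm.sites["chrom"].iloc[sl], gm.sites["pos"].iloc[sl]))
            if self.site_index.get(chrom) != keys:
                raise ImputeError(
                    f"site list of chromosome {chrom} does not match the fitted model"
                )
        if set(self.site_index) != set(gm.chroms):
            raise ImputeError("chromosome sets differ between matrix and model")


def fit_markov(gm: GenotypeMatrix, pseudocount: float = 0.5) -> MarkovModel:
    """Estimate transition tables from lines non-missing at both pair sites."""
    bad = ~np.isin(gm.calls, (MAJOR, MINOR, MISSING))
    if bad.any():
        raise ImputeError("fit_markov requires a post-QC matrix ({0, 2, missing})")
    site_index, transitions, marginals = {}, {}, {}
    for chrom, sl in gm.chrom_slices().items():
        block = gm.calls[:, sl]
        keys = list(zip(gm.sites["chrom"].iloc[sl], gm.sites["pos"].iloc[sl]))
        site_index[chrom] = keys
        m = block.shape[1]
        obs = block != MISSING
        state = (block == MINOR).astype(np.int8)  # valid only where obs

        marg = np.empty((m, 2))
        n_obs = obs.sum(axis=0)
        n_minor = (obs & (state == 1)).sum(axis=0)
        with np.errstate(invalid="ignore"):
            p1 = np.where(n_obs > 0, n_minor / np.maximum(n_obs, 1), 0.5)
        marg[:, 1] = p1
        marg[:, 0] = 1.0 - p1
        marginals[chrom] = marg

        if m < 2:
            transitions[chrom] = None
            continue
        a, b = state[:, :-1], state[:, 1:]
        both = obs[:, :-1] & obs[:, 1:]
        counts = np.empty((m - 1, 2, 2))
        for i in (0, 1):
            for j in (0, 1):
                counts[:, i, j] = (both & (a == i) & (b == j)).sum(axis=0)
        counts += pseudocount
        transitions[chrom] = counts / counts.sum(axis=2, keepdims=True)
    return MarkovModel(site_index, transitions, marginals, pseudocount)


def _argmax_state(p: np.ndarray) -> np.ndarray:
    """Greedy state choice with ties broken toward the major allele (state 0)."""
    return (p[..., 1] > p[..., 0]).astype(np.int8)


def impute_forward(
    gm: GenotypeMatrix, model: MarkovModel, seed: int | None = None
) -> GenotypeMatrix:
    """Fill every missing call by a deterministic left-to-right forward pass.

    ``seed`` is accepted for interface symmetry with the rest of the pipeline
    but unused: the greedy argmax decoder is fully deterministic.
    """
    model.check_sites(gm)
    out = gm.copy()
    for chrom, sl in gm.chrom_slices().items():
        block = out.calls[:, sl]
        trans = model.transitions[chrom]
        marg = model.marginals[chrom]
        m = block.shape[1]
        # first column: marginal argmax for missing calls
        miss = block[:, 0] == MISSING
        state = (block[:, 0] == MINOR).astype(np.int8)
        if miss.any():
            fill = _argmax_state(marg[0])
            state[miss] = fill
            block[miss, 0] = _CALL_OF[fill]
        for j in range(1, m):
            miss = block[:, j] == MISSING
            if miss.any():
                rows = trans[j - 1][state[miss]]  # (k, 2)
                fill = _argmax_state(rows)
                block[miss, j] = _CALL_OF[fill]
            state = (block[:, j] == MINOR).astype(np.int8)
    assert (out.calls != MISSING).all()
    return out


def estimate_accuracy(
    gm_complete: GenotypeMatrix,
    fraction: float = 0.0622,
    reps: int = 100,
    seed: int = 0,
    refit: bool = True,
):
    """Masked-data imputation accuracy.

    Per repetition: mask ``fraction`` of the cells of the complete matrix,
    fit the Markov model on the masked matrix (``refit=True``, mirroring the
    real use case) or on the complete one, impute, and score the fraction of
    masked cells whose imputed state equals the truth.  Returns
    ``(mean accuracy, per-rep accuracies)``.
    """
    from .sim import mask_genotypes

    if not 0.0 < fraction < 1.0:
        raise ImputeError(f"fraction must lie in (0, 1), got {fraction}")
    if reps < 1:
        raise ImputeError("reps must be >= 1")
    if gm_complete.n_missing():
        raise ImputeError("estimate_accuracy requires a complete matrix")
    full_model = None if refit else fit_markov(gm_complete)
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    accs = np.empty(reps)
    for r in range(reps):
        masked, (rows, cols) = mask_genotypes(gm_complete, fraction, int(rep_seeds[r]))
        model = fit_markov(masked) if refit else full_model
        imputed = impute_forward(masked, model)
        accs[r] = np.mean(
            imputed.calls[rows, cols] == gm_complete.calls[rows, cols]
        )
    return float(accs.mean()), accs
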