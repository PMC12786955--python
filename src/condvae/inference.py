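"""Prior sampling, discretization and frequency ranking of generated conditions.

For a query transformation the trained model is sampled repeatedly from its
prior (5000 draws by default), each decoded head output is discretized into a
valid condition vector (argmax on the one-hot blocks, 0.5 threshold on the
additive bits), and the distinct vectors are ranked by how often they were
generated. Ties are broken by the canonical bitstring order so top-k lists
are reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .conditions import ConditionScheme, ConditionVector
from .model import ConditionCVAE, HeadOutputs

__all__ = ["RankedConditionList", "sample_conditions", "discretize",
           "rank_by_frequency", "predict_conditions"]

DEFAULT_N_DRAWS = 5000


@dataclass
class RankedConditionList:
    """Distinct condition vectors for one query, most-frequent first."""

    entries: list[tuple[ConditionVector, int]]
    query_id: str = ""
    total_draws: int = 0

    def top(self, k: int) -> list[ConditionVector]:
        return [v for v, _ in self.entries[:k]]

    def __len__(self):
        return len(self.entries)


def discretize(outputs: HeadOutputs, scheme: ConditionScheme,
               threshold: float = 0.5) -> ConditionVector:
    """Collapse head probabilities to one valid condition vector.

    Argmax over each simplex head (ties → lowest index, numpy convention);
    an additive bit is set iff its probability ≥ `threshold`. If the scheme
    forbids acid+base and both groups pass the threshold, only the group with
    the larger maximal probability is kept (the model's more confident one).
    """
    cat, add, temp, pres = outputs.as_arrays()
    cat, add, temp, pres = (np.asarray(a).reshape(-1) for a in (cat, add, temp, pres))
    bits = np.zeros(scheme.n_bits, dtype=int)
    bits[scheme.catalyst_slice.start + int(np.argmax(cat))] = 1
    add_on = add >= threshold
    if scheme.forbid_acid_base_together:
        acids, bases = scheme._acid_base_indices()
        if acids and bases and add_on[acids].any() and add_on[bases].any():
            if add[acids].max() >= add[bases].max():
                add_on[bases] = False
            else:
                add_on[acids] = False
    bits[scheme.additive_slice][add_on] = 1
    bits[scheme.temp_slice.start + int(np.argmax(temp))] = 1
    bits[scheme.pressure_slice.start + int(np.argmax(pres))] = 1
    return ConditionVector(tuple(int(b) for b in bits), scheme)


def sample_conditions(model: ConditionCVAE, x: np.ndarray,
                      n_draws: int = DEFAULT_N_DRAWS, seed: int = 0,
                      threshold: float = 0.5,
                      decode_mode: str = "argmax") -> list[ConditionVector]:
    """Draw `n_draws` conditions for descriptor `x` from the model prior.

    Deterministic given `seed`; the latent draws are decoded in one batch.
    ``decode_mode="argmax"`` (default) collapses every head deterministically
    (argmax on the simplices, 0.5 threshold on additive bits, via
    :func:`discretize`): each latent draw yields the jointly most likely
    condition of its latent region, and diversity comes from the prior draws
    crossing region boundaries. ``decode_mode="sample"`` performs full
    ancestral sampling (categorical draw per simplex head, Bernoulli per
    additive bit); it follows the model's conditional distribution more
    closely but, because the heads are conditionally independent given z,
    can emit component combinations that never co-occur.
    """
    if not model.fitted:
        raise RuntimeError("model must be trained before sampling conditions")
    if n_draws < 1:
        raise ValueError("n_draws must be ≥ 1")
    if decode_mode not in ("sample", "argmax"):
        raise ValueError(f"unknown decode_mode {decode_mode!r}")
    rng = np.random.default_rng(seed)
    z = model.sample_prior(n_draws, rng)
    x = np.asarray(x, dtype=np.float64).reshape(1, -1)
    f_out = model.f_net.predict(x) if model.dec_cfg.use_f_net else None
    x_rep = np.repeat(x, n_draws, axis=0)
    f_rep = None if f_out is None else np.repeat(f_out, n_draws, axis=0)
    outputs = model.decode(z, x_rep, f_rep)
    cat, add, temp, pres = outputs.as_arrays()
    if decode_mode == "sample":
        cat_idx = _categorical_rows(cat, rng)
        temp_idx = _categorical_rows(temp, rng)
        pres_idx = _categorical_rows(pres, rng)
        add_bits = (rng.random(add.shape) < add).astype(int)
        out = []
        for i in range(n_draws):
            out.append(_assemble(model.scheme, cat_idx[i], add_bits[i],
                                 temp_idx[i], pres_idx[i], add[i]))
        return out
    out = []
    for i in range(n_draws):
        out.append(discretize(
            HeadOutputs(*(_Row(a[i]) for a in (cat, add, temp, pres))),
            model.scheme, threshold))
    return out


def _categorical_rows(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One categorical draw per row of a row-stochastic matrix."""
    cdf = np.cumsum(p, axis=1)
    cdf /= cdf[:, -1:]
    u = rng.random((p.shape[0], 1))
    return (u > cdf).sum(axis=1)


def _assemble(scheme: ConditionScheme, cat_i: int, add_bits: np.ndarray,
              temp_i: int, pres_i: int, add_probs: np.ndarray) -> ConditionVector:
    bits = np.zeros(scheme.n_bits, dtype=int)
    bits[scheme.catalyst_slice.start + int(cat_i)] = 1
    add_on = add_bits.astype(bool)
    if scheme.forbid_acid_base_together:
        acids, bases = scheme._acid_base_indices()
        if acids and bases and add_on[acids].any() and add_on[bases].any():
            if add_probs[acids].max() >= add_probs[bases].max():
                add_on[bases] = False
            else:
                add_on[acids] = False
    bits[scheme.additive_slice][add_on] = 1
    bits[scheme.temp_slice.start + int(temp_i)] = 1
    bits[scheme.pressure_slice.start + int(pres_i)] = 1
    return ConditionVector(tuple(int(b) for b in bits), scheme)


class _Row:
    """Cheap array holder quacking like a Tensor for discretize()."""

    def __init__(self, data):
        self.data = np.asarray(data)


def rank_by_frequency(samples, query_id: str = "") -> RankedConditionList:
    """Rank distinct sampled vectors by count (desc), bitstring order on ties."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample multiset")
    counts = Counter(samples)
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].sort_key()))
    return RankedConditionList(entries=ordered, query_id=query_id,
                               total_draws=len(samples))


def predict_conditions(model: ConditionCVAE, x: np.ndarray,
                       n_draws: int = DEFAULT_N_DRAWS, seed: int = 0,
                       query_id: str = "") -> RankedConditionList:
    """Convenience wrapper: sample then rank for one query descriptor."""
    return rank_by_frequency(sample_conditions(model, x, n_draws, seed),
                             query_id=query_id)
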