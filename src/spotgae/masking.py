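"""MASK / KEEP / REMASK: input corruption for self-supervised training.

Each training epoch draws a fresh mask plan: ``floor(mask_ratio * N)`` spots
are masked; of those, ``floor(replace_ratio * |masked|)`` receive the raw
features of a uniformly drawn spot (from all spots), and the rest receive a
learnable mask token.  Kept spots are untouched.  Before each decoding view,
latent embeddings are independently re-corrupted: ``floor(remask_ratio * N)``
spots — drawn uniformly, regardless of the input mask — are replaced by a
second learnable token.  Feature replacement never happens in REMASK.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaskPlan", "RemaskPlan",
    "draw_mask_plan", "draw_remask_plan", "apply_mask", "apply_remask",
]


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


@dataclass
class MaskPlan:
    masked_set: np.ndarray          # V~, ordered index list
    keep_set: np.ndarray            # complement
    replace_pairs: list             # (target in masked_set, source in V)
    mask_ratio: float
    replace_ratio: float
    seed: object = None

    def __post_init__(self):
        self.masked_set = np.asarray(self.masked_set, dtype=int)
        self.keep_set = np.asarray(self.keep_set, dtype=int)
        n = len(self.masked_set) + len(self.keep_set)
        union = np.union1d(self.masked_set, self.keep_set)
        if len(union) != n or not np.array_equal(union, np.arange(n)):
            raise ValueError("masked_set and keep_set must partition 0..N-1")
        masked = set(self.masked_set.tolist())
        for t, _ in self.replace_pairs:
            if t not in masked:
                raise ValueError("replace target outside masked_set")

    @property
    def n(self) -> int:
        return len(self.masked_set) + len(self.keep_set)

    @property
    def token_rows(self) -> np.ndarray:
        """Masked rows that receive the mask token (not feature-replaced)."""
        repl = {t for t, _ in self.replace_pairs}
        return np.array([i for i in self.masked_set if i not in repl], dtype=int)


@dataclass
class RemaskPlan:
    remask_set: np.ndarray
    ratio: float
    seed: object = None

    def __post_init__(self):
        self.remask_set = np.asarray(self.remask_set, dtype=int)


def draw_mask_plan(n: int, mask_ratio: float = 0.5,
                   replace_ratio: float = 0.05,
                   rng_seed=0) -> MaskPlan:
    """Sample a mask plan; reproducible given the seed (or Generator)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0 <= mask_ratio <= 1 and 0 <= replace_ratio <= 1):
        raise ValueError("ratios must be in [0, 1]")
    rng = _as_rng(rng_seed)
    n_mask = int(np.floor(mask_ratio * n))
    perm = rng.permutation(n)
    masked = np.sort(perm[:n_mask])
    keep = np.sort(perm[n_mask:])
    n_replace = int(np.floor(replace_ratio * n_mask))
    replace_pairs = []
    if n_replace > 0:
        targets = rng.choice(masked, size=n_replace, replace=False)
        sources = rng.integers(0, n, size=n_replace)
        replace_pairs = list(zip(targets.tolist(), sources.tolist()))
    return MaskPlan(masked, keep, replace_pairs, mask_ratio, replace_ratio,
                    seed=rng_seed if not isinstance(rng_seed, np.random.Generator)
                    else None)


def apply_mask(X: np.ndarray, plan: MaskPlan, token: np.ndarray) -> np.ndarray:
    """Build the corrupted feature matrix X~.

    Kept rows are copied unchanged; replace-target rows get the source spot's
    original features; the remaining masked rows get the token.
    """
    X = np.asarray(X)
    token = np.asarray(token)
    if token.shape != (X.shape[1],):
        raise ValueError(f"token length {token.shape} != feature dim {X.shape[1]}")
    if plan.n != X.shape[0]:
        raise ValueError("plan size does not match matrix rows")
    out = X.copy()
    out[plan.token_rows] = token
    for tgt, src in plan.replace_pairs:
        out[tgt] = X[src]
    return out


def draw_remask_plan(n: int, ratio: float = 0.5, rng_seed=0) -> RemaskPlan:
    """Uniform re-corruption draw, independent of any mask plan."""
    if not (0 <= ratio <= 1):
        raise ValueError("ratio must be in [0, 1]")
    rng = _as_rng(rng_seed)
    n_remask = int(np.floor(ratio * n))
    remask = np.sort(rng.permutation(n)[:n_remask])
    return RemaskPlan(remask, ratio,
                      seed=rng_seed if not isinstance(rng_seed, np.random.Generator)
                      else None)


def apply_remask(H: np.ndarray, plan: RemaskPlan,
                 token_h: np.ndarray) -> np.ndarray:
    """Replace remasked rows of the embedding with the shared token."""
    H = np.asarray(H)
    token_h = np.asarray(token_h)
    if token_h.shape != (H.shape[1],):
        raise ValueError("remask token dimension mismatch")
    out = H.copy()
    out[plan.remask_set] = token_h
    return out
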