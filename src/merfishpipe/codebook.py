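"""Combinatorial barcode (codebook) design for multiplexed FISH.

A MERFISH codebook is a set of binary barcodes of length ``n_bits`` with
constant Hamming weight (number of "on" bits) and a guaranteed minimum
pairwise Hamming distance, so single-bit readout errors can be detected or
corrected. The classic choice is the MHD4 code: 20 bits, weight 4, minimum
distance 4.

Codes are built greedily from a shuffled enumeration of all constant-weight
words; many shuffles are tried and the code with the most balanced per-bit
usage is kept. Genes are then assigned to barcodes by a hill-climbing swap
search that evens out the expected molecule density per bit.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Codebook",
    "enumerate_constant_weight",
    "greedy_mhd_code",
    "generate_codebook",
    "assign_genes",
    "bit_load_variance",
]


def enumerate_constant_weight(n_bits: int, weight: int) -> np.ndarray:
    """All C(n_bits, weight) binary words with exactly ``weight`` on-bits.

    Returns a (n_words, n_bits) uint8 array in lexicographic order of
    on-bit positions.
    """
    if weight < 0 or weight > n_bits:
        raise ValueError(f"weight {weight} out of range for {n_bits} bits")
    combos = list(itertools.combinations(range(n_bits), weight))
    out = np.zeros((len(combos), n_bits), dtype=np.uint8)
    for i, positions in enumerate(combos):
        out[i, list(positions)] = 1
    return out


def _to_masks(barcodes: np.ndarray) -> np.ndarray:
    """Pack bit-vector rows into uint64 masks for popcount arithmetic."""
    bits = np.asarray(barcodes, dtype=np.uint64)
    weights = np.uint64(1) << np.arange(bits.shape[1], dtype=np.uint64)
    return bits @ weights


def min_pairwise_distance(barcodes: np.ndarray) -> int:
    """Minimum Hamming distance over all pairs (full pairwise scan)."""
    masks = _to_masks(barcodes)
    best = barcodes.shape[1] + 1
    for i in range(len(masks) - 1):
        d = np.bitwise_count(masks[i + 1 :] ^ masks[i]).min()
        best = min(best, int(d))
    return best


def greedy_mhd_code(
    candidates: np.ndarray, min_distance: int, seed: int = 0
) -> np.ndarray:
    """Greedy minimum-distance code from a seeded shuffle of ``candidates``.

    The candidate order is shuffled, the first word is kept, and each
    subsequent word is kept iff its Hamming distance to every kept word is
    at least ``min_distance``. For constant-weight words all pairwise
    distances are even, so ``min_distance`` is normally even too.
    """
    candidates = np.asarray(candidates, dtype=np.uint8)
    if candidates.shape[0] == 0:
        return candidates.reshape(0, candidates.shape[1] if candidates.ndim == 2 else 0)
    rng = np.random.default_rng(seed)
    order = rng.permutation(candidates.shape[0])
    shuffled = candidates[order]
    masks = _to_masks(shuffled)

    kept_masks = np.empty(len(masks), dtype=np.uint64)
    kept_idx = np.empty(len(masks), dtype=np.int64)
    kept_masks[0] = masks[0]
    kept_idx[0] = 0
    n_kept = 1
    for i in range(1, len(masks)):
        d = np.bitwise_count(kept_masks[:n_kept] ^ masks[i])
        if int(d.min()) >= min_distance:
            kept_masks[n_kept] = masks[i]
            kept_idx[n_kept] = i
            n_kept += 1
    return shuffled[kept_idx[:n_kept]]


@dataclass
class Codebook:
    """A constant-weight barcode set with an optional gene assignment."""

    n_bits: int
    weight: int
    min_distance: int
    barcodes: np.ndarray
    gene_assignment: dict[str, int] = field(default_factory=dict)
    trial_scores: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.barcodes = np.asarray(self.barcodes, dtype=np.uint8)
        w = self.barcodes.sum(axis=1)
        if self.barcodes.size and not np.all(w == self.weight):
            raise ValueError("barcode with wrong Hamming weight")
        if len(self.gene_assignment) != len(set(self.gene_assignment.values())):
            raise ValueError("gene assignment is not injective")

    @property
    def n_barcodes(self) -> int:
        return self.barcodes.shape[0]

    @property
    def bit_usage(self) -> np.ndarray:
        """Per-bit count of on-bits over all codewords."""
        return self.barcodes.sum(axis=0).astype(int)

    def on_bits(self, gene: str) -> tuple[int, ...]:
        """0-based on-bit indices of a gene's barcode (its readout ids)."""
        code = self.barcodes[self.gene_assignment[gene]]
        return tuple(int(i) for i in np.flatnonzero(code))

    def validate(self) -> None:
        """Assert weight and minimum pairwise distance by full scan."""
        if self.n_barcodes >= 2 and min_pairwise_distance(self.barcodes) < self.min_distance:
            raise ValueError("pairwise Hamming distance below minimum")

    # -- serialization -------------------------------------------------------
    def to_json(self, path: str | Path, bit_names: list[str] | None = None) -> None:
        payload = {
            "version": "1",
            "n_bits": self.n_bits,
            "weight": self.weight,
            "min_distance": self.min_distance,
            "bit_names": bit_names or [f"bit{i + 1}" for i in range(self.n_bits)],
            "barcodes": ["".join(map(str, row)) for row in self.barcodes],
            "gene_map": dict(self.gene_assignment),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Codebook":
        payload = json.loads(Path(path).read_text())
        barcodes = np.array(
            [[int(c) for c in row] for row in payload["barcodes"]], dtype=np.uint8
        )
        return cls(
            n_bits=payload["n_bits"],
            weight=payload["weight"],
            min_distance=payload["min_distance"],
            barcodes=barcodes,
            gene_assignment={g: int(i) for g, i in payload["gene_map"].items()},
        )


def generate_codebook(
    n_bits: int = 20,
    weight: int = 4,
    min_distance: int = 4,
    n_trials: int = 500,
    min_size: int = 200,
    seed: int = 0,
) -> Codebook:
    """Best-of-``n_trials`` greedy codebook generation.

    Each trial reshuffles the full constant-weight enumeration with a
    distinct seed and builds a greedy code. Among trials reaching
    ``min_size`` codewords, the code with the lowest population variance of
    per-bit usage is returned; its per-trial scores are attached.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    candidates = enumerate_constant_weight(n_bits, weight)
    sizes, variances, codes = [], [], []
    for t in range(n_trials):
        code = greedy_mhd_code(candidates, min_distance, seed=seed + t)
        usage = code.sum(axis=0)
        sizes.append(code.shape[0])
        variances.append(float(np.var(usage)))
        codes.append(code)
    scores = pd.DataFrame({"trial": range(n_trials), "size": sizes, "bit_usage_var": variances})
    eligible = scores[scores["size"] >= min_size]
    if eligible.empty:
        raise ValueError(
            f"no trial reached min_size={min_size}; best size achieved was {max(sizes)}"
        )
    best = int(eligible.sort_values(["bit_usage_var", "trial"]).iloc[0]["trial"])
    return Codebook(
        n_bits=n_bits,
        weight=weight,
        min_distance=min_distance,
        barcodes=codes[best],
        trial_scores=scores,
    )


def bit_load_variance(
    barcodes: np.ndarray, assignment: np.ndarray, gene_expression: np.ndarray
) -> float:
    """Variance across bits of total expected molecule density per bit.

    ``assignment[g]`` is the barcode index of gene ``g``;
    ``gene_expression[g]`` the abundance-weighted mean expression.
    """
    loads = gene_expression @ barcodes[assignment].astype(float)
    return float(np.var(loads))


def assign_genes(
    codebook: Codebook,
    mean_expression: pd.DataFrame,
    type_abundance: pd.Series | None = None,
    seed: int = 0,
    max_sweeps: int = 200,
) -> dict[str, int]:
    """Assign genes to barcodes, balancing expected molecule load per bit.

    ``mean_expression`` is genes x cell types; ``type_abundance`` weights the
    per-type means into one expected expression per gene. Starting from a
    seeded random assignment, pairwise swaps (gene-gene, and gene to unused
    barcode) are proposed in random-order sweeps; a swap is kept iff it
    strictly decreases the variance of per-bit load. The search stops when a
    full sweep yields no improvement, so the objective is non-increasing.
    """
    genes = list(mean_expression.index)
    if len(genes) > codebook.n_barcodes:
        raise ValueError(
            f"{len(genes)} genes exceed the {codebook.n_barcodes} available barcodes"
        )
    if type_abundance is None:
        type_abundance = pd.Series(1.0, index=mean_expression.columns)
    w = type_abundance.reindex(mean_expression.columns).to_numpy(dtype=float)
    expr = mean_expression.to_numpy(dtype=float) @ (w / w.sum())

    rng = np.random.default_rng(seed)
    n_genes, n_codes = len(genes), codebook.n_barcodes
    barcodes = codebook.barcodes.astype(float)
    assignment = rng.permutation(n_codes)[:n_genes]
    loads = expr @ barcodes[assignment]

    def var_of(loads_vec: np.ndarray) -> float:
        return float(np.var(loads_vec))

    current = var_of(loads)
    slots = list(range(n_genes)) + [-k - 1 for k in range(n_codes - n_genes)]
    for _ in range(max_sweeps):
        improved = False
        pairs = [(i, j) for i in range(len(slots)) for j in range(i + 1, len(slots)) if i < n_genes]
        rng.shuffle(pairs)
        used = set(assignment.tolist())
        free = [b for b in range(n_codes) if b not in used]
        for i, j in pairs:
            if j < n_genes:  # swap two genes' barcodes
                new_loads = (
                    loads
                    + expr[i] * (barcodes[assignment[j]] - barcodes[assignment[i]])
                    + expr[j] * (barcodes[assignment[i]] - barcodes[assignment[j]])
                )
                if var_of(new_loads) < current - 1e-12:
                    assignment[i], assignment[j] = assignment[j], assignment[i]
                    loads, current = new_loads, var_of(new_loads)
                    improved = True
            else:  # move gene i to an unused barcode
                k = j - n_genes
                if k >= len(free):
                    continue
                b = free[k]
                new_loads = loads + expr[i] * (barcodes[b] - barcodes[assignment[i]])
                if var_of(new_loads) < current - 1e-12:
                    free[k] = int(assignment[i])
                    assignment[i] = b
                    loads, current = new_loads, var_of(new_loads)
                    improved = True
        if not improved:
            break
    return {g: int(b) for g, b in zip(genes, assignment)}
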