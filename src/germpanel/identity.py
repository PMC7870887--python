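"""Identity-by-state similarity and accession verification.

The similarity between two samples is the mean, over sites where both are
called, of per-site allele sharing ``1 - |g_i - g_j| / 2`` with dosage
codes g in {0, 1, 2}.  With heterozygotes masked beforehand (the normal
workflow for inbred germplasm) this is the simple matching fraction of
homozygous calls.  Pairs sharing fewer than ``min_shared`` co-called sites
are flagged invalid rather than reported as numbers.

Verification compares every query accession against its *expected*
counterpart (same accession identifier in the other platform's panel) and
the best match actually observed, and issues one of six verdicts:

``CONFIRMED``
    top match is the expected counterpart at >= ``confirm`` similarity.
``DRIFTED``
    expected counterpart is still the top match but similarity sits below
    ``confirm`` (e.g. seed lots grown out separately for generations).
``REDUNDANT_CONSISTENT``
    a different accession edges out the expected one, but the expected
    similarity is >= ``floor`` and the winning margin is <= ``gap``
    (genetically redundant germplasm groups).
``MIS_ASSIGNED``
    the observed top match beats the expected counterpart by more than
    ``gap`` — a labeling or tracking error.
``UNIQUE``
    no expected counterpart and no match >= ``floor``.
``NO_EXPECTED``
    no expected counterpart, yet some accession matches at >= ``floor``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel

VERDICTS = (
    "CONFIRMED",
    "DRIFTED",
    "REDUNDANT_CONSISTENT",
    "MIS_ASSIGNED",
    "UNIQUE",
    "NO_EXPECTED",
)

DEFAULT_CONFIRM = 0.99
DEFAULT_FLOOR = 0.90
DEFAULT_GAP = 0.03
DEFAULT_MIN_SHARED = 100


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise identity fractions plus co-called site counts."""

    samples: list[str]
    sim: np.ndarray
    n_shared: np.ndarray
    min_shared: int

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of pairs with enough co-called sites to be meaningful."""
        return self.n_shared >= self.min_shared

    def index(self, sample_id: str) -> int:
        try:
            return self.samples.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in similarity matrix") from None

    def get(self, a: str, b: str) -> float:
        return float(self.sim[self.index(a), self.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sim, index=self.samples, columns=self.samples)


def ibs_similarity(
    panel: GenotypePanel, min_shared: int = DEFAULT_MIN_SHARED
) -> SimilarityMatrix:
    """Compute the all-pairs identity-by-state matrix of a panel.

    sim[i, j] = mean over co-called sites of ``1 - |g_i - g_j| / 2``; the
    diagonal is 1 for any sample with at least one non-missing call.
    Entries with no co-called sites are NaN.
    """
    G = panel.geno
    valid = (G >= 0).astype(np.float64)
    a0 = (G == 0).astype(np.float64)
    a1 = (G == 1).astype(np.float64)
    a2 = (G == 2).astype(np.float64)

    n_shared = valid @ valid.T
    agree = a0 @ a0.T + a1 @ a1.T + a2 @ a2.T
    half = a0 @ a1.T + a1 @ a0.T + a1 @ a2.T + a2 @ a1.T
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(n_shared > 0, (agree + 0.5 * half) / n_shared, np.nan)
    return SimilarityMatrix(
        samples=list(panel.samples),
        sim=sim,
        n_shared=n_shared.astype(np.int64),
        min_shared=int(min_shared),
    )


def top_matches(
    matrix: SimilarityMatrix,
    queries: list[str] | None = None,
    references: list[str] | None = None,
    k: int = 1,
) -> tuple[dict[str, list[tuple[str, float]]], list[str]]:
    """Rank, for each query, its k most similar references (self excluded).

    Ties are broken by lexicographic reference ID.  Pairs below the
    ``min_shared`` validity threshold are not ranked.  Queries absent from
    the matrix are returned in the error list instead of raising.
    """
    queries = list(queries) if queries is not None else list(matrix.samples)
    references = list(references) if references is not None else list(matrix.samples)
    valid = matrix.valid
    errors: list[str] = []
    out: dict[str, list[tuple[str, float]]] = {}
    ref_idx = [(r, matrix.index(r)) for r in references if r in matrix.samples]
    for q in queries:
        try:
            qi = matrix.index(q)
        except KeyError:
            errors.append(q)
            continue
        cands = [
            (r, float(matrix.sim[qi, ri]))
            for r, ri in ref_idx
            if r != q and valid[qi, ri] and np.isfinite(matrix.sim[qi, ri])
        ]
        cands.sort(key=lambda t: (-t[1], t[0]))
        out[q] = cands[: max(0, int(k))]
    return out, errors


def classify_accessions(
    matrix: SimilarityMatrix,
    expected: dict[str, str | None],
    queries: list[str] | None = None,
    references: list[str] | None = None,
    confirm: float = DEFAULT_CONFIRM,
    floor: float = DEFAULT_FLOOR,
    gap: float = DEFAULT_GAP,
) -> pd.DataFrame:
    """Issue one verification verdict per query accession.

    Parameters
    ----------
    expected:
        Map query ID -> expected counterpart ID (or None for accessions
        known to lack a counterpart).  Counterparts absent from the matrix
        are treated as missing.
    queries, references:
        Default to the keys of ``expected`` and all matrix samples.

    Returns a MatchReport DataFrame with columns query, expected,
    expected_sim, top_match, top_sim, gap, n_shared, verdict.  The verdict
    assignment is total and deterministic; gap = top_sim - expected_sim is
    >= 0 whenever the expected counterpart is a valid reference, because
    top_sim is the maximum over references.
    """
    queries = list(queries) if queries is not None else list(expected.keys())
    ranked, errors = top_matches(matrix, queries=queries, references=references, k=1)

    rows = []
    for q in queries:
        if q in errors:
            rows.append(
                dict(query=q, expected=expected.get(q), expected_sim=np.nan,
                     top_match=None, top_sim=np.nan, gap=np.nan, n_shared=0,
                     verdict="UNIQUE")
            )
            continue
        exp_id = expected.get(q)
        if exp_id is not None and exp_id not in matrix.samples:
            exp_id = None
        hits = ranked.get(q, [])
        top_id, top_sim = (hits[0] if hits else (None, np.nan))
        if exp_id is not None:
            qi, ei = matrix.index(q), matrix.index(exp_id)
            exp_sim = float(matrix.sim[qi, ei]) if matrix.valid[qi, ei] else np.nan
            n_shared = int(matrix.n_shared[qi, ei])
            if not np.isfinite(exp_sim):
                exp_id = None  # too little overlap to use the counterpart
        if exp_id is None:
            exp_sim = np.nan
            n_shared = (
                int(matrix.n_shared[matrix.index(q), matrix.index(top_id)])
                if top_id is not None
                else 0
            )
            verdict = (
                "NO_EXPECTED"
                if (top_id is not None and top_sim >= floor)
                else "UNIQUE"
            )
            margin = np.nan
        else:
            margin = (top_sim - exp_sim) if np.isfinite(top_sim) else 0.0
            if margin > gap:
                verdict = "MIS_ASSIGNED"
            elif top_id == exp_id or top_id is None:
                verdict = "CONFIRMED" if exp_sim >= confirm else "DRIFTED"
            elif exp_sim >= floor:
                verdict = "REDUNDANT_CONSISTENT"
            else:
                verdict = "DRIFTED"
        rows.append(
            dict(query=q, expected=exp_id, expected_sim=exp_sim, top_match=top_id,
                 top_sim=top_sim, gap=margin, n_shared=n_shared, verdict=verdict)
        )
    report = pd.DataFrame(
        rows,
        columns=["query", "expected", "expected_sim", "top_match", "top_sim",
                 "gap", "n_shared", "verdict"],
    )
    return report


def verdict_counts(report: pd.DataFrame) -> dict[str, int]:
    counts = {v: 0 for v in VERDICTS}
    counts.update(report["verdict"].value_counts().to_dict())
    return counts
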