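"""Ligand-based target prediction from chemical structure.

Compounds are encoded as 2048-bit radius-2 circular fingerprints
(ECFP4-equivalent Morgan fingerprints); similarity is the Tanimoto
coefficient.  Per (target, activity threshold), the probability of the
query being active is a similarity-weighted k-nearest-neighbour vote
over the bioactivity corpus, a transparent predictor exposing the same
interface as the pre-trained classifier stacks used for target fishing:
probability, applicability-domain percentile and the nearest training
neighbour with its similarity.  Activity thresholds follow the potency
convention: a record is active at threshold T when its measured value is
at most T uM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

DEFAULT_NBITS = 2048
DEFAULT_THRESHOLDS = (0.1, 1.0, 10.0, 100.0)

#: locally recorded structures, keyed by accession.  Only structures whose
#: identity is public knowledge are recorded; asking for an accession that
#: is not registered raises, it is never guessed.
ACCESSION_SMILES: dict[str, str] = {
    # anle138b: 3-(1,3-benzodioxol-5-yl)-5-(3-bromophenyl)-1H-pyrazole
    "anle138b": "Brc1cccc(c1)-c1cc(-c2ccc3OCOc3c2)[nH]n1",
}


class SmilesParseError(ValueError):
    pass


class UnknownAccessionError(KeyError):
    pass


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length bit-set fingerprint.

    ``source`` records whether the bits came from a chemical structure
    or were generated synthetically.
    """

    bits: frozenset[int]
    nbits: int = DEFAULT_NBITS
    source: str = "structure"

    def __post_init__(self) -> None:
        if self.bits and max(self.bits) >= self.nbits:
            raise ValueError("bit index out of range")

    def to_hex(self) -> str:
        arr = bytearray(self.nbits // 8)
        for b in self.bits:
            arr[b // 8] |= 1 << (b % 8)
        return bytes(arr).hex()

    @classmethod
    def from_hex(cls, s: str, source: str = "synthetic") -> "Fingerprint":
        raw = bytes.fromhex(s)
        bits = {
            i * 8 + j for i, byte in enumerate(raw) for j in range(8) if byte >> j & 1
        }
        return cls(bits=frozenset(bits), nbits=len(raw) * 8, source=source)


# -- fingerprinting -----------------------------------------------------------


def fingerprint(smiles: str, nbits: int = DEFAULT_NBITS) -> Fingerprint:
    """Radius-2 circular (ECFP4-equivalent) fingerprint of a SMILES string."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        pos = _parse_failure_position(smiles)
        raise SmilesParseError(
            f"could not parse SMILES (first failing position ~{pos}): {smiles!r}"
        )
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=nbits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint(bits=frozenset(fp.GetOnBits()), nbits=nbits, source="structure")


def _parse_failure_position(smiles: str) -> int:
    """Best-effort index of the first character at which no prefix parses."""
    for i in range(1, len(smiles) + 1):
        if Chem.MolFromSmiles(smiles[:i], sanitize=False) is not None:
            continue
        return i - 1
    return len(smiles)


def fingerprint_accession(accession: str, nbits: int = DEFAULT_NBITS) -> Fingerprint:
    """Fingerprint a compound by accession from the local structure registry."""
    try:
        smi = ACCESSION_SMILES[accession]
    except KeyError:
        raise UnknownAccessionError(
            f"no structure recorded for accession {accession!r}; "
            "fetch it and add it to ACCESSION_SMILES"
        ) from None
    return fingerprint(smi, nbits=nbits)


# -- similarity ---------------------------------------------------------------


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |a n b| / |a u b|.

    Symmetric; 1 iff the (non-empty) bit sets are identical; two empty
    fingerprints are defined to have similarity 0.
    """
    if a.nbits != b.nbits:
        raise ValueError("fingerprints have different lengths")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


# -- synthetic fingerprints (for generated corpora) ---------------------------


def random_fingerprint(
    nbits: int, density: float = 0.1, rng: np.random.Generator | None = None
) -> Fingerprint:
    rng = np.random.default_rng(rng)
    k = max(1, round(nbits * density))
    bits = rng.choice(nbits, size=k, replace=False)
    return Fingerprint(bits=frozenset(int(b) for b in bits), nbits=nbits, source="synthetic")


def neighbour_fingerprint(
    query: Fingerprint, similarity: float, rng: np.random.Generator | None = None
) -> Fingerprint:
    """A fingerprint with (approximately) the requested Tanimoto to ``query``.

    Keeps m of the query's q bits and adds q - m fresh bits, so the
    coefficient is m / (2q - m); m is the rounding of the exact solution
    q * 2t / (1 + t).
    """
    if not 0 < similarity <= 1:
        raise ValueError("similarity must lie in (0, 1]")
    rng = np.random.default_rng(rng)
    q = len(query.bits)
    m = round(q * 2 * similarity / (1 + similarity))
    keep = rng.choice(sorted(query.bits), size=m, replace=False)
    free = sorted(set(range(query.nbits)) - query.bits)
    add = rng.choice(free, size=q - m, replace=False)
    bits = frozenset(int(b) for b in keep) | frozenset(int(b) for b in add)
    return Fingerprint(bits=bits, nbits=query.nbits, source="synthetic")


# -- target prediction ---------------------------------------------------------


def _corpus_fingerprints(corpus: pd.DataFrame) -> dict[str, Fingerprint]:
    fps: dict[str, Fingerprint] = {}
    for cid, grp in corpus.groupby("compound_id"):
        if "fingerprint" in grp.columns and isinstance(
            grp["fingerprint"].iloc[0], Fingerprint
        ):
            fps[cid] = grp["fingerprint"].iloc[0]
        else:
            fps[cid] = Fingerprint.from_hex(grp["fingerprint_hex"].iloc[0])
    return fps


def predict_targets(
    query: Fingerprint,
    corpus: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    k: int = 5,
) -> pd.DataFrame:
    """Similarity-weighted kNN target prediction at each activity threshold.

    ``corpus`` columns: compound_id, fingerprint_hex (or fingerprint),
    target_id, activity_uM.  Per (target, threshold), the k corpus
    compounds with bioactivity data for that target that are most
    similar to the query vote with weight = their Tanimoto similarity:
    probability = sum(T_i * y_i) / sum(T_i), y_i = activity <= threshold.
    Similarity ties are broken by compound id.  The nearest training
    neighbour per target is reported alongside an applicability-domain
    percentile of the query against that target's training compounds.
    """
    if corpus.empty:
        raise ValueError("empty bioactivity corpus")
    if (corpus["activity_uM"] <= 0).any():
        raise ValueError("activity values must be positive")
    fps = _corpus_fingerprints(corpus)
    sims = {cid: tanimoto(query, fp) for cid, fp in fps.items()}
    rows = []
    for target, grp in corpus.groupby("target_id", sort=True):
        grp = grp.drop_duplicates(subset="compound_id")
        order = sorted(grp["compound_id"], key=lambda c: (-sims[c], c))
        nn = order[0]
        train_fps = [fps[c] for c in order]
        ad = applicability_percentile(query, train_fps, k=k) if len(train_fps) >= 2 else 0.0
        knn = order[:k]
        w = np.array([sims[c] for c in knn])
        act = grp.set_index("compound_id")["activity_uM"]
        for thr in thresholds:
            y = np.array([act[c] <= thr for c in knn], dtype=float)
            prob = float(w @ y / w.sum()) if w.sum() > 0 else 0.0
            rows.append(
                {
                    "target_id": target,
                    "threshold_uM": thr,
                    "probability": prob,
                    "ad_percentile": ad,
                    "nn_id": nn,
                    "nn_similarity": sims[nn],
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["probability", "target_id"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )


def applicability_percentile(
    query: Fingerprint, training: Sequence[Fingerprint], k: int = 5
) -> float:
    """Applicability-domain percentile of a query against training chemistry.

    The statistic is the mean Tanimoto similarity to the k nearest
    training compounds; the reference distribution is the same statistic
    for every training compound against the rest (leave-self-out); the
    percentile is 100 x the fraction of reference values <= the query's.
    """
    if len(training) < 2:
        raise ValueError("need at least 2 training fingerprints")

    def stat(fp: Fingerprint, others: Iterable[Fingerprint]) -> float:
        s = sorted((tanimoto(fp, o) for o in others), reverse=True)
        return float(np.mean(s[:k]))

    ref = [stat(t, [o for j, o in enumerate(training) if j != i]) for i, t in enumerate(training)]
    q = stat(query, training)
    return 100.0 * float(np.mean([r <= q for r in ref]))


# -- pharmacokinetic arithmetic -------------------------------------------------


def unbound_cmax(cmax_total: float, fraction_unbound: float) -> float:
    """Maximum unbound concentration: total Cmax x fraction unbound (uM)."""
    if cmax_total < 0 or fraction_unbound < 0:
        raise ValueError("inputs must be non-negative")
    if fraction_unbound > 1:
        raise ValueError("fraction unbound cannot exceed 1")
    return cmax_total * fraction_unbound
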