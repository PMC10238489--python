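"""Splice-isoform frequency estimation from exon-junction read counts.

Reads spanning an exon-exon junction are informative about which isoforms
are expressed: each junction appears only in the isoforms in which the two
exons are consecutive.  With junction counts ``c_j`` and a 0/1 membership
matrix ``M`` (junctions x isoforms), relative isoform frequencies ``f`` are
estimated by non-negative least squares on ``c_j ~ lambda * sum_i M_ji f_i``
with a free global scale, then normalised to sum to one.  A companion
utility classifies single-base codon substitutions (synonymous / missense /
nonsense), e.g. a CAG (glutamine) to TAG (stop) change in an alternatively
spliced exon.

Junction-count tables are TSV with columns ``donor_exon``, ``acceptor_exon``
and ``count``; isoform models are JSON mapping isoform ids to ordered exon
lists.  Read mapping is upstream and out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "IsoformModel",
    "JunctionCounts",
    "IsoformFrequencies",
    "junction_matrix",
    "estimate_isoform_frequencies",
    "simulate_junction_counts",
    "isoform_ratio",
    "classify_codon_substitution",
    "CodonEffect",
    "GENETIC_CODE",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class IsoformModel:
    """Transcript structures: isoform id -> ordered list of exon identifiers."""

    isoforms: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.isoforms:
            raise ValueError("model must contain at least one isoform")
        for iso, exons in self.isoforms.items():
            if len(exons) < 2:
                raise ValueError(f"isoform {iso!r} must have at least 2 exons")
            if len(set(exons)) != len(exons):
                raise ValueError(f"isoform {iso!r} repeats an exon")

    def junctions(self) -> list[tuple[str, str]]:
        """All distinct consecutive exon pairs across the model, sorted."""
        seen = set()
        for exons in self.isoforms.values():
            seen.update(zip(exons[:-1], exons[1:]))
        return sorted(seen)

    @classmethod
    def from_json(cls, path) -> "IsoformModel":
        with open(path) as fh:
            data = json.load(fh)
        return cls(isoforms={k: list(v) for k, v in data.items()})

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.isoforms, fh, indent=1)


@dataclass
class JunctionCounts:
    """Read counts per (donor exon, acceptor exon) junction."""

    counts: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for junc, c in self.counts.items():
            if c < 0:
                raise ValueError(f"negative count for junction {junc}")

    @classmethod
    def from_tsv(cls, path) -> "JunctionCounts":
        df = pd.read_csv(path, sep="\t", dtype={"donor_exon": str, "acceptor_exon": str})
        required = {"donor_exon", "acceptor_exon", "count"}
        if not required.issubset(df.columns):
            raise ValueError(f"junction table must have columns {sorted(required)}")
        return cls(
            counts={
                (str(r.donor_exon), str(r.acceptor_exon)): float(r.count)
                for r in df.itertuples()
            }
        )

    def to_tsv(self, path) -> None:
        rows = [
            {"donor_exon": d, "acceptor_exon": a, "count": c}
            for (d, a), c in sorted(self.counts.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class IsoformFrequencies:
    """Normalised relative isoform frequencies plus fit diagnostics."""

    frequencies: dict[str, float]
    residual_norm: float
    novel_junctions: list[tuple[str, str]]
    non_identifiable: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        total = sum(self.frequencies.values())
        if self.frequencies and not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError("frequencies must sum to 1")
        if any(f < -1e-12 for f in self.frequencies.values()):
            raise ValueError("frequencies must be non-negative")

    def __getitem__(self, isoform: str) -> float:
        return self.frequencies[isoform]


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------


def junction_matrix(model: IsoformModel) -> pd.DataFrame:
    """0/1 membership matrix, junctions (rows) x isoforms (columns).

    Entry 1 means the junction's exon pair is consecutive in the isoform.
    """
    juncs = model.junctions()
    isoforms = sorted(model.isoforms)
    mat = np.zeros((len(juncs), len(isoforms)), dtype=int)
    index = {j: i for i, j in enumerate(juncs)}
    for col, iso in enumerate(isoforms):
        exons = model.isoforms[iso]
        for pair in zip(exons[:-1], exons[1:]):
            mat[index[pair], col] = 1
    df = pd.DataFrame(mat, index=pd.MultiIndex.from_tuples(juncs, names=["donor", "acceptor"]), columns=isoforms)
    if df.index.duplicated().any():
        raise ValueError("duplicate junction rows in the model")
    return df


def _duplicate_column_groups(mat: pd.DataFrame) -> list[tuple[str, ...]]:
    groups: dict[bytes, list[str]] = {}
    for col in mat.columns:
        groups.setdefault(mat[col].to_numpy().tobytes(), []).append(col)
    return [tuple(cols) for cols in groups.values() if len(cols) > 1]


def estimate_isoform_frequencies(
    counts: JunctionCounts, model: IsoformModel
) -> IsoformFrequencies:
    """Estimate relative isoform frequencies from junction counts by NNLS.

    Junctions observed in the counts but absent from the model are reported
    as novel rather than silently dropped; isoforms with identical junction
    signatures (indistinguishable by any junction) are flagged
    non-identifiable.
    """
    mat = junction_matrix(model)
    modelled = set(mat.index)
    novel = sorted(j for j in counts.counts if j not in modelled)
    c = np.array([counts.counts.get(j, 0.0) for j in mat.index], dtype=float)
    if not np.any(c > 0):
        raise ValueError("all junction counts on modelled junctions are zero")
    x, resid = optimize.nnls(mat.to_numpy(dtype=float), c)
    total = x.sum()
    if total <= 0:
        raise ValueError("degenerate fit: all isoform weights are zero")
    freqs = {iso: float(x[i] / total) for i, iso in enumerate(mat.columns)}
    return IsoformFrequencies(
        frequencies=freqs,
        residual_norm=float(resid),
        novel_junctions=novel,
        non_identifiable=_duplicate_column_groups(mat),
    )


def isoform_ratio(freqs: IsoformFrequencies, a: str, b: str) -> float:
    """Relative mRNA level ratio frequency(a) / frequency(b)."""
    fb = freqs[b]
    if fb <= 0:
        raise ValueError(f"isoform {b!r} has zero estimated frequency")
    return freqs[a] / fb


def simulate_junction_counts(
    model: IsoformModel,
    frequencies: dict[str, float],
    n_reads: int,
    rng: np.random.Generator | int | None = None,
) -> JunctionCounts:
    """Draw multinomial junction-spanning reads for known isoform frequencies.

    Under uniform read coverage every junction of a transcript receives
    reads in proportion to the transcript's abundance, so the expected count
    of junction j is proportional to sum_i M_ji f_i.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mat = junction_matrix(model)
    f = np.array([frequencies.get(iso, 0.0) for iso in mat.columns], dtype=float)
    if f.sum() <= 0:
        raise ValueError("frequencies must have positive mass")
    f = f / f.sum()
    m = mat.to_numpy(dtype=float)
    probs = m @ f
    probs = probs / probs.sum()
    draw = rng.multinomial(n_reads, probs)
    return JunctionCounts(counts={j: float(k) for j, k in zip(mat.index, draw)})


# ---------------------------------------------------------------------------
# codon substitution effects
# ---------------------------------------------------------------------------

#: standard genetic code, DNA alphabet, '*' = stop
GENETIC_CODE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class CodonEffect:
    ref_codon: str
    alt_codon: str
    ref_aa: str
    alt_aa: str
    effect_class: str  # synonymous | missense | nonsense


def classify_codon_substitution(ref_codon: str, position_in_codon: int, alt_base: str) -> CodonEffect:
    """Classify a single-base codon substitution under the standard code.

    ``nonsense`` means the substitution converts an amino-acid codon into a
    stop codon (e.g. CAG -> TAG, glutamine to stop); a stop-to-stop change
    counts as synonymous, and stop-to-amino-acid (readthrough) as missense.
    """
    ref_codon = str(ref_codon).upper()
    alt_base = str(alt_base).upper()
    if len(ref_codon) != 3 or any(b not in "ACGT" for b in ref_codon):
        raise ValueError(f"invalid reference codon {ref_codon!r}")
    if alt_base not in "ACGT":
        raise ValueError(f"invalid substituted base {alt_base!r}")
    if not 0 <= position_in_codon <= 2:
        raise ValueError("position_in_codon must be 0, 1 or 2")
    if ref_codon[position_in_codon] == alt_base:
        raise ValueError("substitution must change the base")
    alt_codon = ref_codon[:position_in_codon] + alt_base + ref_codon[position_in_codon + 1 :]
    ref_aa = GENETIC_CODE[ref_codon]
    alt_aa = GENETIC_CODE[alt_codon]
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*" and ref_aa != "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return CodonEffect(ref_codon, alt_codon, ref_aa, alt_aa, effect)
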