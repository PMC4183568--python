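"""In silico digestion of end-labelled amplicons.

A TRFLP measurement sees only the fragment between a fluorescently labelled
primer end and the nearest restriction cut. This module predicts that
fragment for complete digestion, enumerates the longer fragments that
incomplete digestion can produce (pseudo-TRFs, which inflate apparent
richness), and summarises amplicon length/GC composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

from .enzymes import (
    DEFAULT_CHANNEL_RULE,
    DEFAULT_ENZYMES,
    RestrictionEnzyme,
    find_recognition_sites,
    reverse_complement,
)

__all__ = [
    "GenotypeRecord",
    "TRFPrediction",
    "TRFTable",
    "terminal_fragment_length",
    "enumerate_pseudo_trfs",
    "characterize_sequences",
    "predict_trf_table",
    "infer_dye_end_map",
]

LengthConvention = Literal["labelled_strand", "duplex_mean"]


@dataclass(frozen=True)
class GenotypeRecord:
    """One amplicon genotype with its dye-to-end assignment.

    ``dye_end_map`` maps a dye name (e.g. ``"HEX"``) to ``"left"`` (position 0
    of the stored strand) or ``"right"`` (the last position). In the AM1/NS31
    assay HEX sits on the AM1 end and FAM on the NS31 end.
    """

    id: str
    sequence: str
    dye_end_map: dict[str, str] = field(
        default_factory=lambda: {"HEX": "left", "FAM": "right"}
    )

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        ends = list(self.dye_end_map.values())
        if any(e not in ("left", "right") for e in ends):
            raise ValueError(f"{self.id}: ends must be 'left' or 'right'")
        if len(ends) == 2 and ends[0] == ends[1]:
            raise ValueError(f"{self.id}: both dyes assigned to the same end")

    def __len__(self) -> int:
        return len(self.sequence)

    def oriented_sequence(self, dye: str) -> str:
        """The sequence read 5'→3' from the labelled end of `dye`."""
        try:
            end = self.dye_end_map[dye]
        except KeyError:
            raise KeyError(
                f"{self.id}: unknown dye {dye!r}; available: "
                f"{sorted(self.dye_end_map)}"
            ) from None
        return self.sequence if end == "left" else reverse_complement(self.sequence)


@dataclass(frozen=True)
class TRFPrediction:
    """Predicted fragments for one genotype × enzyme × dye channel."""

    genotype_id: str
    enzyme_name: str
    dye: str
    complete_trf_bp: float
    pseudo_trfs_bp: frozenset[float]

    def __post_init__(self) -> None:
        if any(p <= self.complete_trf_bp for p in self.pseudo_trfs_bp):
            raise ValueError(
                f"{self.genotype_id}/{self.enzyme_name}: pseudo-TRFs must be "
                "longer than the complete-digest TRF"
            )


def _cut_coordinates(
    oriented: str, enzyme: RestrictionEnzyme, convention: LengthConvention
) -> list[float]:
    """Ascending cut coordinates measured from the labelled 5' end."""
    if convention == "labelled_strand":
        offset: float = enzyme.cut_offset
    elif convention == "duplex_mean":
        offset = enzyme.duplex_cut_offset()
    else:
        raise ValueError(f"unknown length convention {convention!r}")
    return [s + offset for s in find_recognition_sites(oriented, enzyme)]


def terminal_fragment_length(
    record: GenotypeRecord,
    enzyme: RestrictionEnzyme,
    dye: str,
    convention: LengthConvention = "labelled_strand",
) -> float:
    """Complete-digest terminal fragment length for one dye channel, in bp.

    The distance from the labelled end to the nearest cut; the full amplicon
    length when the enzyme has no site. ``duplex_mean`` averages the two
    strand cut coordinates within the site (half-integers for enzymes with
    odd-length sites such as HinfI); ``labelled_strand`` uses the cut on the
    labelled strand itself.
    """
    oriented = record.oriented_sequence(dye)
    cuts = _cut_coordinates(oriented, enzyme, convention)
    return cuts[0] if cuts else float(len(oriented))


def enumerate_pseudo_trfs(
    record: GenotypeRecord,
    enzyme: RestrictionEnzyme,
    dye: str,
    convention: LengthConvention = "labelled_strand",
) -> set[float]:
    """All labelled-end fragment lengths achievable by missed cuts.

    Skipping any subset of recognition sites leaves the labelled fragment
    ending at the nearest *retained* cut (or running the full length when
    every site is skipped), so the reachable lengths are the distances to
    each cut beyond the first, plus the full length — minus the
    complete-digest length itself. Site-free amplicons have no pseudo-TRFs.
    """
    oriented = record.oriented_sequence(dye)
    cuts = _cut_coordinates(oriented, enzyme, convention)
    if not cuts:
        return set()
    lengths = set(cuts[1:]) | {float(len(oriented))}
    lengths.discard(cuts[0])
    return lengths


def characterize_sequences(records: Sequence[GenotypeRecord]) -> pd.DataFrame:
    """Per-amplicon length and GC content, with exact min/max summaries.

    Returns a DataFrame indexed by genotype id with columns ``length_bp`` and
    ``gc_percent`` (to one decimal place, as conventionally reported), and
    ``.attrs`` carrying ``length_min/max`` and ``gc_min/max``.
    """
    if not records:
        raise ValueError("characterize_sequences requires at least one record")
    rows = {}
    for rec in records:
        seq = rec.sequence
        gc = 100.0 * (seq.count("G") + seq.count("C")) / len(seq)
        rows[rec.id] = {"length_bp": len(seq), "gc_percent": round(gc, 1)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "genotype_id"
    df.attrs.update(
        length_min=int(df["length_bp"].min()),
        length_max=int(df["length_bp"].max()),
        gc_min=float(df["gc_percent"].min()),
        gc_max=float(df["gc_percent"].max()),
    )
    return df


def infer_dye_end_map(sequence: str, primers: Mapping[str, str]) -> dict[str, str]:
    """Locate each labelled primer's end of the amplicon by best end-match.

    For every dye → primer-sequence pair, the primer is compared (simple
    base identity) against the left end of the stored strand and its
    reverse complement against the right end; the better-matching end wins.
    The two dyes of a dual-labelled amplicon must resolve to opposite ends,
    otherwise the orientation is ambiguous and an error is raised (use an
    explicit ``dye_end_map`` to override).
    """
    seq = sequence.upper()

    def score(a: str, b: str) -> float:
        return sum(x == y for x, y in zip(a, b)) / max(len(a), 1)

    out: dict[str, str] = {}
    for dye, primer in primers.items():
        p = primer.upper()
        left = score(p, seq[: len(p)])
        right = score(reverse_complement(p), seq[-len(p):])
        out[dye] = "left" if left >= right else "right"
    if len(out) == 2 and len(set(out.values())) == 1:
        raise ValueError(
            f"both primers best-match the same end ({set(out.values())}); "
            "supply dye_end_map explicitly"
        )
    return out


@dataclass
class TRFTable:
    """Predicted TRFs for a set of genotypes across enzyme channels.

    ``collisions`` lists (enzyme, length, [genotype ids]) for any complete
    TRF length shared by two or more genotypes under the same enzyme — a
    violation of the design criterion that genotypes be distinguishable.
    """

    predictions: list[TRFPrediction]
    collisions: list[tuple[str, float, list[str]]] = field(default_factory=list)

    @property
    def has_collisions(self) -> bool:
        return bool(self.collisions)

    def for_enzyme(self, enzyme_name: str) -> list[TRFPrediction]:
        return [p for p in self.predictions if p.enzyme_name == enzyme_name]

    def lookup(self, genotype_id: str, enzyme_name: str) -> TRFPrediction:
        for p in self.predictions:
            if p.genotype_id == genotype_id and p.enzyme_name == enzyme_name:
                return p
        raise KeyError(f"no prediction for {genotype_id!r} × {enzyme_name!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype_id": p.genotype_id,
                "enzyme": p.enzyme_name,
                "dye": p.dye,
                "complete_trf_bp": p.complete_trf_bp,
                "pseudo_trfs_bp": ";".join(
                    f"{x:g}" for x in sorted(p.pseudo_trfs_bp)
                ),
            }
            for p in self.predictions
        )


def predict_trf_table(
    records: Iterable[GenotypeRecord],
    enzymes: dict[str, RestrictionEnzyme] | None = None,
    channel_rule: dict[str, str] | None = None,
    convention: LengthConvention = "labelled_strand",
) -> TRFTable:
    """Predict complete and pseudo TRFs for every genotype × enzyme channel.

    Each enzyme is read in the dye channel `channel_rule` assigns to it
    (default: HEX for AluI, FAM for HinfI). Genotype pairs sharing a complete
    TRF length for an enzyme are flagged in ``collisions``.
    """
    enzymes = DEFAULT_ENZYMES if enzymes is None else enzymes
    channel_rule = DEFAULT_CHANNEL_RULE if channel_rule is None else channel_rule
    predictions: list[TRFPrediction] = []
    for rec in records:
        for enz_name, enzyme in enzymes.items():
            dye = channel_rule[enz_name]
            predictions.append(
                TRFPrediction(
                    genotype_id=rec.id,
                    enzyme_name=enz_name,
                    dye=dye,
                    complete_trf_bp=terminal_fragment_length(
                        rec, enzyme, dye, convention
                    ),
                    pseudo_trfs_bp=frozenset(
                        enumerate_pseudo_trfs(rec, enzyme, dye, convention)
                    ),
                )
            )
    collisions: list[tuple[str, float, list[str]]] = []
    by_key: dict[tuple[str, float], list[str]] = {}
    for p in predictions:
        by_key.setdefault((p.enzyme_name, p.complete_trf_bp), []).append(p.genotype_id)
    for (enz, length), ids in sorted(by_key.items()):
        if len(ids) > 1:
            collisions.append((enz, length, sorted(ids)))
    return TRFTable(predictions=predictions, collisions=collisions)
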