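"""Published summary tables from the Rya WWTP activated-sludge Archaea survey.

These are the printed per-OTU clone counts and matched TRF size pairs of the
original study, transcribed as plain tuples so the headline diversity
statistics can be recomputed without the (unshipped) raw sequence data.
"""

from __future__ import annotations

# Per-OTU clone counts of the 82-clone 16S rRNA library at the 98.7%
# (species-level) similarity threshold: 25 OTUs, 82 clones.
CLONE_OTU_COUNTS: tuple[int, ...] = (15, 12, 8, 6, 5, 4, 4, 4, 4, 2, 2, 2, 2) + (1,) * 12

# The 13 OTUs classified as Methanosaeta in the phylogenetic analysis
# (63 of the 82 clones).
METHANOSAETA_OTU_COUNTS: tuple[int, ...] = (15, 12, 8, 6, 5, 4, 4, 2, 2, 2, 1, 1, 1)

# Matched (enzyme, predicted, observed) TRF length pairs between the in-silico
# digest of the clone library and the T-RFLP profile of the same sample.
# Predicted TRFs run consistently longer than observed ones.
MATCHED_TRF_PAIRS: tuple[tuple[str, int, int], ...] = (
    ("AluI", 188, 183),
    ("RsaI", 80, 74),
    ("RsaI", 242, 238),
)


def clone_otu_counts() -> list[int]:
    """Species-level per-OTU clone counts (descending), as a fresh list."""
    return list(CLONE_OTU_COUNTS)


def methanosaeta_otu_counts() -> list[int]:
    """Clone counts of the Methanosaeta-assigned OTUs, as a fresh list."""
    return list(METHANOSAETA_OTU_COUNTS)


def matched_trf_pairs() -> list[tuple[str, int, int]]:
    """Matched (enzyme, predicted, observed) TRF pairs, as a fresh list."""
    return list(MATCHED_TRF_PAIRS)
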