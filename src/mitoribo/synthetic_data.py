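"""Seeded generators for every fixture the pipeline needs.

The generator emulates the mixed-species mitoribosome-profiling design: human
(target) and mouse (spike-in) lysates combined 95:5, sequenced as ribosome
protected fragments (RPF) and matched RNA libraries, for a knockout (KO)
versus rescue contrast with programmable per-transcript RNA-abundance and
translation-efficiency effects.

Mixing model
------------
Each feature class carries an *absolute* sampling weight.  Target transcript
``f`` weighs ``abundance x rna_fold x te_fold x length_nt`` (the fold terms
apply only in the KO condition; ``te_fold`` only for RPF libraries, since
footprint density is proportional to abundance times translation efficiency).
The spike-in class has a fixed weight calibrated so that its read share
equals ``spike_read_fraction`` in the baseline (rescue) condition.  Because
the spike-in weight does not move with the knockout, it anchors absolute
abundances exactly as a physical spike-in does: when KO lowers the
mitochondrial transcriptome, the spike-in share of reads rises, and
spike-normalized quantities recover the programmed fold changes.

The same mechanism emulates whole-cell RNAseq, where the invariant class
plays the (much larger) non-mitochondrial background: with
``spike_read_fraction = 0.95`` the total read depth is an approximately
invariant anchor and depth (CPM) normalization recovers abundance folds, as
in the whole-cell analysis this models.

Determinism: every generator output is a pure function of its arguments,
including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .io_formats import (
    AlignmentRecord,
    Annotation,
    Feature,
    PLDDTProfile,
    PresenceMatrix,
    SequenceRecord,
    SpeciesTree,
    parse_newick,
)

__all__ = [
    "MITO_CDS_LENGTHS",
    "SPIKE_LENGTHS",
    "WHOLE_CELL_BACKGROUND_FRACTION",
    "KOPreset",
    "LibrarySpec",
    "make_mito_annotation",
    "default_ko_preset",
    "identity_preset",
    "sample_library",
    "library_specs_for_contrast",
    "whole_cell_rna_specs",
    "presence_matrix_fixture",
    "planted_motif_sequences",
    "plddt_profile_fixture",
]

# Human mitochondrial CDS lengths (nt, incl. stop), rounded to the RefSeq
# rCRS gene models; these set realistic per-transcript read shares.
MITO_CDS_LENGTHS: dict[str, int] = {
    "MT-ND1": 956,
    "MT-ND2": 1042,
    "MT-CO1": 1542,
    "MT-CO2": 684,
    "MT-ATP8": 207,
    "MT-ATP6": 681,
    "MT-CO3": 784,
    "MT-ND3": 346,
    "MT-ND4L": 297,
    "MT-ND4": 1378,
    "MT-ND5": 1812,
    "MT-ND6": 525,
    "MT-CYB": 1141,
}

# Mouse spike-in stand-ins (lengths on the order of mito CDS lengths).
SPIKE_LENGTHS: dict[str, int] = {
    "mm-SPIKE1": 1500,
    "mm-SPIKE2": 1000,
    "mm-SPIKE3": 700,
}

_LIGHT_STRAND = {"MT-ND6"}
_GAP = 50  # intergenic gap between laid-out features

# Baseline read share of the invariant (non-mitochondrial) class when
# emulating whole-cell RNAseq; mito reads are a minor share of a whole-cell
# library, which is what makes depth normalization an abundance anchor.
WHOLE_CELL_BACKGROUND_FRACTION = 0.95

RPF_LENGTH_RANGE = (20, 45)
RNA_LENGTH_RANGE = (50, 150)


@dataclass(frozen=True)
class KOPreset:
    """Per-transcript KO effects relative to rescue.

    ``rna_fold`` multiplies a transcript's abundance in KO (<1 = reduction);
    ``te_fold`` multiplies its translation efficiency in KO.
    """

    rna_fold: Mapping[str, float]
    te_fold: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, table in (("rna_fold", self.rna_fold), ("te_fold", self.te_fold)):
            for fid, v in table.items():
                if not np.isfinite(v) or v <= 0:
                    raise ValueError(f"{name}[{fid}] must be finite and positive, got {v}")

    def validate_against(self, annotation: Annotation) -> None:
        targets = {f.feature_id for f in annotation.target_features}
        for name, table in (("rna_fold", self.rna_fold), ("te_fold", self.te_fold)):
            missing = targets - set(table)
            if missing:
                raise ValueError(f"{name} missing entries for {sorted(missing)}")


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of one simulated sequencing library."""

    library_id: str
    assay: str  # RPF | RNA
    condition: str  # rescue | KO
    n_reads: int
    spike_read_fraction: float = 0.05
    seed: int = 0
    rpf_length_mean: float = 33.0
    rpf_length_sd: float = 2.0
    softclip_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.assay not in ("RPF", "RNA"):
            raise ValueError(f"assay must be RPF or RNA, got {self.assay!r}")
        if self.condition not in ("rescue", "KO"):
            raise ValueError(f"condition must be rescue or KO, got {self.condition!r}")
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not (0.0 < self.spike_read_fraction < 1.0):
            raise ValueError(
                f"spike_read_fraction must lie in (0,1), got {self.spike_read_fraction}"
            )
        if not (0.0 <= self.softclip_prob < 1.0):
            raise ValueError("softclip_prob must lie in [0,1)")


def make_mito_annotation(
    lengths: Mapping[str, int] | None = None,
    spike_lengths: Mapping[str, int] | None = None,
    reference_name: str = "mito_toy",
) -> Annotation:
    """The 13-transcript mitochondrial mRNA annotation plus spike-in features.

    All 13 mtDNA-encoded coding sequences are laid out consecutively (with
    intergenic gaps) on a single toy reference; MT-ND6 is the only
    light-strand feature.  Lengths default to the human gene models and are
    individually overridable.
    """
    base = dict(MITO_CDS_LENGTHS)
    if lengths:
        unknown = set(lengths) - set(base)
        if unknown:
            raise ValueError(f"unknown transcript(s) in length override: {sorted(unknown)}")
        base.update(lengths)
    spikes = dict(spike_lengths or SPIKE_LENGTHS)

    features = []
    cursor = 0
    for fid, ln in base.items():
        strand = "light" if fid in _LIGHT_STRAND else "heavy"
        features.append(Feature(fid, "target", strand, cursor, cursor + ln))
        cursor += ln + _GAP
    for fid, ln in spikes.items():
        features.append(Feature(fid, "spikein", "spikein", cursor, cursor + ln))
        cursor += ln + _GAP
    return Annotation(tuple(features), reference_name=reference_name)


# Fold *reductions* of heavy-strand transcript abundance in KO, strongest for
# the cytochrome c oxidase class; extremes 1.6x (MT-ND1) and 3.8x (MT-CO1)
# sit inside the observed 1.5-4-fold range.  ND3 is stable and the
# light-strand ND6 unaffected.
_DEFAULT_RNA_REDUCTION: dict[str, float] = {
    "MT-CO1": 3.8,
    "MT-CO2": 3.4,
    "MT-CO3": 3.0,
    "MT-CYB": 2.6,
    "MT-ND5": 2.4,
    "MT-ATP6": 2.2,
    "MT-ND4": 2.0,
    "MT-ND2": 1.9,
    "MT-ATP8": 1.8,
    "MT-ND4L": 1.7,
    "MT-ND1": 1.6,
}


def default_ko_preset() -> KOPreset:
    """The documented default KO effect table.

    RNA abundance: heavy-strand transcripts reduced 1.6-3.8-fold (table
    above); MT-ND3 and MT-ND6 unchanged.  TE: MT-CO1 and MT-CO2 reduced
    2.5-fold (multiplier 0.4), MT-ND6 increased 2.5-fold, all others
    unchanged.
    """
    rna = {fid: 1.0 for fid in MITO_CDS_LENGTHS}
    for fid, reduction in _DEFAULT_RNA_REDUCTION.items():
        rna[fid] = 1.0 / reduction
    te = {fid: 1.0 for fid in MITO_CDS_LENGTHS}
    te["MT-CO1"] = 0.4
    te["MT-CO2"] = 0.4
    te["MT-ND6"] = 2.5
    return KOPreset(rna_fold=rna, te_fold=te)


def identity_preset() -> KOPreset:
    """A preset with all folds 1 (KO indistinguishable from rescue)."""
    ones = {fid: 1.0 for fid in MITO_CDS_LENGTHS}
    return KOPreset(rna_fold=dict(ones), te_fold=dict(ones))


def _feature_weights(
    spec: LibrarySpec, annotation: Annotation, preset: KOPreset | None
) -> tuple[list[Feature], np.ndarray]:
    """Absolute sampling weights for every feature under this library spec."""
    targets = annotation.target_features
    spikes = annotation.spikein_features
    base = np.array([f.length_nt for f in targets], dtype=float)  # abundance 1 each
    weights = base.copy()
    if spec.condition == "KO" and preset is not None:
        preset.validate_against(annotation)
        rna = np.array([preset.rna_fold[f.feature_id] for f in targets])
        weights = weights * rna
        if spec.assay == "RPF":
            te = np.array([preset.te_fold[f.feature_id] for f in targets])
            weights = weights * te
    # Invariant class: fixed weight, calibrated on the baseline target mass so
    # that its read share equals spike_read_fraction in the rescue condition.
    f = spec.spike_read_fraction
    spike_total = f / (1.0 - f) * base.sum()
    spike_lens = np.array([s.length_nt for s in spikes], dtype=float)
    spike_w = spike_total * spike_lens / spike_lens.sum()
    feats = list(targets) + list(spikes)
    return feats, np.concatenate([weights, spike_w])


def _draw_lengths(
    spec: LibrarySpec, n: int, rng: np.random.Generator, max_len: np.ndarray
) -> np.ndarray:
    if spec.assay == "RPF":
        lo, hi = RPF_LENGTH_RANGE
        lengths = np.rint(rng.normal(spec.rpf_length_mean, spec.rpf_length_sd, size=n))
        lengths = np.clip(lengths, lo, hi).astype(int)
    else:
        lo, hi = RNA_LENGTH_RANGE
        lengths = rng.integers(lo, hi + 1, size=n)
    return np.minimum(lengths, max_len)


def sample_library(
    spec: LibrarySpec,
    annotation: Annotation,
    preset: KOPreset | None = None,
) -> Iterator[AlignmentRecord]:
    """Stream seeded alignment records for one library.

    Reads are multinomial over features with the weights described in the
    module docstring; start positions are uniform within the feature such
    that the aligned span fits; RPF lengths follow a discretized normal
    truncated to [20, 45] nt and RNA lengths a wider uniform range; with
    probability ``softclip_prob`` a 1-5 nt soft clip is added on a random
    side.  The KO preset applies only when ``condition == "KO"``.
    """
    rng = np.random.default_rng(spec.seed)
    feats, weights = _feature_weights(spec, annotation, preset)
    probs = weights / weights.sum()
    starts = np.array([f.start for f in feats])
    lens = np.array([f.length_nt for f in feats])
    ref = annotation.reference_name

    chunk = 100_000
    emitted = 0
    while emitted < spec.n_reads:
        n = min(chunk, spec.n_reads - emitted)
        which = rng.choice(len(feats), size=n, p=probs)
        max_len = lens[which]
        rlen = _draw_lengths(spec, n, rng, max_len)
        offs = rng.integers(0, lens[which] - rlen + 1)
        pos = starts[which] + offs + 1  # 1-based SAM POS
        clip = rng.random(n) < spec.softclip_prob
        clip_len = rng.integers(1, 6, size=n)
        clip_side = rng.integers(0, 2, size=n)  # 0 = prepend, 1 = append
        for i in range(n):
            L = int(rlen[i])
            if clip[i]:
                s = (("S", int(clip_len[i])),)
                cigar = s + (("M", L),) if clip_side[i] == 0 else (("M", L),) + s
            else:
                cigar = (("M", L),)
            yield AlignmentRecord(
                query_id=f"{spec.library_id}:r{emitted + i}",
                reference_name=ref,
                pos=int(pos[i]),
                cigar=cigar,
                library_id=spec.library_id,
            )
        emitted += n


def library_specs_for_contrast(
    n_reads: int,
    seed: int,
    spike_read_fraction: float = 0.05,
    rpf_length_mean_rescue: float = 33.0,
    rpf_length_mean_ko: float = 31.0,
    rpf_length_sd: float = 2.0,
    softclip_prob: float = 0.1,
) -> list[LibrarySpec]:
    """The four matched libraries of the KO-vs-rescue profiling design.

    Seeds fork deterministically from ``seed`` by a stable per-library offset
    so adding a library never perturbs existing ones.
    """
    combos = [("RPF", "rescue"), ("RPF", "KO"), ("RNA", "rescue"), ("RNA", "KO")]
    specs = []
    for k, (assay, cond) in enumerate(combos):
        mean = rpf_length_mean_rescue if cond == "rescue" else rpf_length_mean_ko
        specs.append(
            LibrarySpec(
                library_id=f"{assay.lower()}_{cond}",
                assay=assay,
                condition=cond,
                n_reads=n_reads,
                spike_read_fraction=spike_read_fraction,
                seed=seed * 8 + k,
                rpf_length_mean=mean,
                rpf_length_sd=rpf_length_sd,
                softclip_prob=softclip_prob,
            )
        )
    return specs


def whole_cell_rna_specs(n_reads: int, seed: int) -> tuple[LibrarySpec, LibrarySpec]:
    """Rescue and KO whole-cell RNAseq libraries.

    The invariant feature class stands in for the non-mitochondrial
    transcriptome at a 95% baseline read share, so total read depth is an
    approximately invariant anchor and CPM fold changes recover the
    programmed abundance folds.
    """
    common = dict(
        assay="RNA",
        n_reads=n_reads,
        spike_read_fraction=WHOLE_CELL_BACKGROUND_FRACTION,
        softclip_prob=0.05,
    )
    rescue = LibrarySpec(library_id="wc_rna_rescue", condition="rescue", seed=seed * 8 + 4, **common)
    ko = LibrarySpec(library_id="wc_rna_ko", condition="KO", seed=seed * 8 + 5, **common)
    return rescue, ko


# ---------------------------------------------------------------------------
# Ortholog presence/absence fixture
# ---------------------------------------------------------------------------

_FIXTURE_NEWICK = (
    "((((((((Hs,Ds)Bilateria,Nv)Eumetazoa,Ta)Parahoxozoa,Aq)Metazoa,Mb)Choanozoa,"
    "Co)Holozoa,Sc)Opisthokonta,Rp)Root;"
)

_METAZOA = ["Hs", "Ds", "Nv", "Ta", "Aq"]
_ALL_SPECIES = ["Hs", "Ds", "Nv", "Ta", "Aq", "Mb", "Co", "Sc", "Rp"]


def presence_matrix_fixture() -> tuple[SpeciesTree, PresenceMatrix]:
    """Nine-species ladder tree and the protein presence/absence matrix.

    LRPPRC and mS31 are present in exactly the five metazoan leaves, mS39 in
    the metazoan leaves, and SLIRP in {Hs, Ds, Nv} plus a tentative
    (uncertain) call in Trichoplax (Ta).
    """
    import pandas as pd

    tree = parse_newick(_FIXTURE_NEWICK)
    presence = pd.DataFrame(False, index=["LRPPRC", "SLIRP", "mS31", "mS39"], columns=_ALL_SPECIES)
    presence.loc["LRPPRC", _METAZOA] = True
    presence.loc["mS31", _METAZOA] = True
    presence.loc["mS39", _METAZOA] = True
    presence.loc["SLIRP", ["Hs", "Ds", "Nv", "Ta"]] = True
    uncertain = pd.DataFrame(False, index=presence.index, columns=presence.columns)
    uncertain.loc["SLIRP", "Ta"] = True
    return tree, PresenceMatrix(presence, uncertain)


# ---------------------------------------------------------------------------
# Motif-planted protein sequences
# ---------------------------------------------------------------------------

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _instantiate(pattern: str, rng: np.random.Generator) -> str:
    """Replace wildcards with random residues; letters kept (uppercased)."""
    out = []
    for ch in pattern:
        if ch == "x":
            out.append(str(rng.choice(_AA)))
        else:
            out.append(ch.upper())
    return "".join(out)


def planted_motif_sequences(
    seed: int,
    plants: Sequence[tuple[str, int]] | None = None,
    length: int = 200,
    n_extra_background: int = 2,
) -> tuple[list[SequenceRecord], list[tuple[str, str, int]]]:
    """Random background sequences with motifs planted at recorded positions.

    ``plants`` is a list of (motif pattern, 1-based position); each plant goes
    into its own sequence.  Returns the records plus the ground-truth list of
    (seq_id, pattern, position).  Background residues are uniform over the 20
    amino acids, so accidental extra hits are possible — ground truth lists
    planted positions only, and scanner output is checked to *contain* them.
    """
    rng = np.random.default_rng(seed)
    if plants is None:
        plants = [("PTRELA", 10), ("DExD", 100), ("GFxxPxxIQ", 42)]
    records: list[SequenceRecord] = []
    truth: list[tuple[str, str, int]] = []
    for i, (pattern, pos1) in enumerate(plants):
        motif = _instantiate(pattern, rng)
        if pos1 < 1 or pos1 - 1 + len(motif) > length:
            raise ValueError(f"plant {pattern!r} at {pos1} does not fit in length {length}")
        seq = rng.choice(_AA, size=length)
        seq[pos1 - 1 : pos1 - 1 + len(motif)] = list(motif)
        sid = f"planted_{i}"
        records.append(SequenceRecord(sid, "".join(seq)))
        truth.append((sid, pattern, pos1))
    for j in range(n_extra_background):
        seq = "".join(rng.choice(_AA, size=length))
        records.append(SequenceRecord(f"background_{j}", seq))
    return records, truth


# ---------------------------------------------------------------------------
# Segmented pLDDT profiles
# ---------------------------------------------------------------------------


def plddt_profile_fixture(
    breakpoints: Sequence[int],
    segment_params: Sequence[Sequence[float]],
    noise_sd: float,
    seed: int,
    start_index: int = 1,
) -> tuple[PLDDTProfile, list[int]]:
    """Piecewise-polynomial mean profile plus Gaussian noise, clipped to [0,100].

    ``breakpoints`` are the last residue indices of every segment (the final
    entry is the profile's last residue); ``segment_params[k]`` are the
    polynomial coefficients (constant first) of segment k, evaluated on the
    within-segment offset 0..len-1.  Returns the profile and the ground-truth
    internal breakpoints (all but the final entry).
    """
    breakpoints = list(breakpoints)
    if sorted(breakpoints) != breakpoints or len(set(breakpoints)) != len(breakpoints):
        raise ValueError("breakpoints must be strictly increasing")
    if len(breakpoints) != len(segment_params):
        raise ValueError("need one parameter set per segment")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    prev = start_index - 1
    for last, coefs in zip(breakpoints, segment_params):
        n = last - prev
        if n < 1:
            raise ValueError("segment of non-positive length")
        x = np.arange(n, dtype=float)
        mean = np.zeros(n)
        for k, c in enumerate(coefs):
            mean += c * x**k
        values.extend(mean)
        prev = last
    arr = np.asarray(values)
    if noise_sd > 0:
        arr = arr + rng.normal(0.0, noise_sd, size=arr.size)
    arr = np.clip(arr, 0.0, 100.0)
    idx = np.arange(start_index, start_index + arr.size)
    return PLDDTProfile(idx, arr), breakpoints[:-1]
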