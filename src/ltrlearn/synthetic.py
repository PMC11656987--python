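"""Synthetic LTR-like datasets with planted, recoverable structure.

Positives emulate the organization of real plant LTRs: superfamily-
specific terminal tetramers extending the canonical TG..CA edges
(Ty1/Copia TGTT..AACA, Ty3/Gypsy TGAT..ATCA), a TATAWA box at a
configurable internal position (central by default), and family-specific
motif instances sampled from per-family PWMs, all on a uniform or
Markov background.  Negatives follow the negative-set recipes: uniform
random sequences, windows from a patchy-GC synthetic genome, and order-2
Markov resamples of the positives (trained per family, the known ground-
truth grouping standing in for similarity clustering).

Every planted coordinate is recorded in a truth table so featurization
and explainability claims can be scored against ground truth.  A
``signal_strength`` dial blends planted motif columns toward the uniform
background (1 = full information, 0 = indistinguishable), which yields
matched datasets of graded difficulty for monotonicity experiments.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .negset import MarkovModel, train_markov
from .seqio import ALPHABET, LabeledSequence, PWMotif

DEFAULT_EDGES = {"Ty1/Copia": ("TGTT", "AACA"), "Ty3/Gypsy": ("TGAT", "ATCA")}

DEFAULT_FAMILY_SUPERFAMILY = {
    "Ale": "Ty1/Copia", "Alesia": "Ty1/Copia", "Angela": "Ty1/Copia", "Bianca": "Ty1/Copia",
    "Ikeros": "Ty1/Copia", "Ivana": "Ty1/Copia", "SIRE": "Ty1/Copia", "TAR": "Ty1/Copia",
    "Tork": "Ty1/Copia", "Athila": "Ty3/Gypsy", "CRM": "Ty3/Gypsy", "Galadriel": "Ty3/Gypsy",
    "Reina": "Ty3/Gypsy", "Retand": "Ty3/Gypsy", "Tekay": "Ty3/Gypsy",
}

_BASES = np.array(list(ALPHABET))


def consensus_pwm(name: str, consensus: str, p_major=0.95) -> PWMotif:
    """A sharp PWM around a consensus string.

    ``p_major`` may be a scalar or a per-column vector; slightly varied
    per-column sharpness keeps relative-threshold scanning away from
    exact score ties.
    """
    w = len(consensus)
    p = np.broadcast_to(np.asarray(p_major, dtype=float), (w,))
    m = np.empty((4, w))
    for j, b in enumerate(consensus):
        m[:, j] = (1 - p[j]) / 3
        m[ALPHABET.index(b), j] = p[j]
    return PWMotif(name, m, kind="probabilities")


def _random_consensus(rng: np.random.Generator, width: int) -> str:
    return "".join(rng.choice(_BASES, size=width))


@dataclass
class SyntheticSpec:
    """Study conditions of a synthetic dataset.

    Defaults: 15 families split 9 Ty1/Copia / 6 Ty3/Gypsy, lengths
    300-3000 bp, TATA box at 0.45 of the length, one shared LTR-core
    motif planted twice per positive plus 3 family-specific motifs, and
    equal thirds of random / genomic-like / Markov-resampled negatives.
    """

    n_positive: int = 200
    n_negative: int = 200
    length_range: tuple = (300, 3000)
    family_superfamily: dict = field(default_factory=lambda: dict(DEFAULT_FAMILY_SUPERFAMILY))
    superfamily_edges: dict = field(default_factory=lambda: dict(DEFAULT_EDGES))
    tata_fraction: float = 0.45
    # conserved bases inward of each terminal tetramer (the 5' end of U3
    # and 3' end of U5 are conserved beyond the TG..CA signature); 0 =
    # tetramer-only termini
    edge_extension: int = 0
    n_shared_motifs: int = 1
    shared_motif_count: int = 2
    n_family_motifs: int = 3
    family_motif_count: int = 1
    motif_width: int = 10
    motif_sharpness: tuple = (0.93, 0.99)  # per-column consensus probability range
    motif_window: tuple = (0.1, 0.9)
    n_decoy_motifs: int = 20
    # Optional hardening for explainability studies: sharing motif
    # content and some edge signatures with the negatives removes
    # single-feature shortcuts, leaving only the LTR-specific
    # organization (shared core motif, consistent TATA position,
    # universal edges).  Defaults follow the plain negative-set recipes.
    negative_edge_fraction: float = 0.0
    negative_edge5_fraction: float | None = None  # default: negative_edge_fraction
    negative_edge3_fraction: float | None = None
    negative_tata_fraction: float = 0.0  # decoy TATAWA at the same relative position
    match_negative_motifs: bool = False
    negative_proportions: dict = field(
        default_factory=lambda: {"random": 1 / 3, "genomic": 1 / 3, "markov": 1 / 3}
    )
    markov_order: int = 2
    background: MarkovModel | None = None  # None = uniform
    signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_range[0] < self.motif_width + 20:
            raise ValueError("minimum length too small for the planted motifs")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        if not 0 < self.tata_fraction < 1:
            raise ValueError("tata_fraction must be a fraction of the length")

    # deterministic motif panels derived from the seed -------------------

    def _motif_rng(self) -> np.random.Generator:
        return np.random.default_rng((self.seed, 0xA11E1E))

    def _draw_pwm(self, rng: np.random.Generator, name: str) -> PWMotif:
        consensus = _random_consensus(rng, self.motif_width)
        sharpness = rng.uniform(*self.motif_sharpness, size=self.motif_width)
        return consensus_pwm(name, consensus, p_major=sharpness)

    def shared_motifs(self) -> list[PWMotif]:
        rng = self._motif_rng()
        return [self._draw_pwm(rng, f"LTR_core_{i}") for i in range(self.n_shared_motifs)]

    def family_motifs(self) -> dict:
        rng = self._motif_rng()
        for i in range(self.n_shared_motifs):
            self._draw_pwm(rng, f"skip_{i}")  # advance past the shared pool
        out = {}
        for fam in sorted(self.family_superfamily):
            out[fam] = [
                self._draw_pwm(rng, f"{fam}_motif_{i}") for i in range(self.n_family_motifs)
            ]
        return out

    def edge_extensions(self) -> dict:
        """Per-superfamily conserved sequence inward of the edge tetramers."""
        rng = np.random.default_rng((self.seed, 0xED6E))
        return {
            sf: (_random_consensus(rng, self.edge_extension),
                 _random_consensus(rng, self.edge_extension))
            for sf in sorted(self.superfamily_edges)
        }

    def decoy_motifs(self) -> list[PWMotif]:
        rng = np.random.default_rng((self.seed, 0xDEC0))
        return [self._draw_pwm(rng, f"decoy_{i}") for i in range(self.n_decoy_motifs)]

    def motif_panel(self) -> list[PWMotif]:
        """The scanning panel: planted shared + family motifs + decoys."""
        panel = list(self.shared_motifs())
        for fam in sorted(self.family_superfamily):
            panel.extend(self.family_motifs()[fam])
        panel.extend(self.decoy_motifs())
        return panel


def _sample_background(rng: np.random.Generator, length: int, background: MarkovModel | None) -> list:
    if background is None:
        return list(rng.choice(_BASES, size=length))
    from .negset import generate_markov

    return list(generate_markov(background, length, rng))


def _sample_motif_instance(rng: np.random.Generator, motif: PWMotif, strength: float) -> str:
    probs = strength * motif.matrix + (1 - strength) * 0.25
    out = []
    for j in range(motif.width):
        p = probs[:, j]
        out.append(ALPHABET[rng.choice(4, p=p / p.sum())])
    return "".join(out)


def generate_dataset(spec: SyntheticSpec):
    """Build (positives, negatives, truth table).

    The truth table records every planted coordinate (0-based, half-open)
    with its kind: edge5 / edge3 / tata / motif.  Regeneration with the
    same spec is byte-identical.
    """
    rng = np.random.default_rng((spec.seed, 0x5E0))
    families = sorted(spec.family_superfamily)
    shared = spec.shared_motifs()
    fam_motifs = spec.family_motifs()
    truth_rows = []
    positives = []
    for i in range(spec.n_positive):
        fam = families[i % len(families)]
        sf = spec.family_superfamily[fam]
        L = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = _sample_background(rng, L, spec.background)
        sid = f"pos_{i}"

        def plant(pattern: str, start: int, kind: str, name: str) -> None:
            seq[start : start + len(pattern)] = list(pattern)
            truth_rows.append({"id": sid, "kind": kind, "name": name,
                               "start": start, "end": start + len(pattern),
                               "family": fam, "superfamily": sf})

        # terminal tetramers (+ conserved extensions), then TATA, then
        # motifs in non-reserved space
        e5, e3 = spec.superfamily_edges[sf]
        ext5, ext3 = spec.edge_extensions()[sf] if spec.edge_extension else ("", "")
        plant(e5 + ext5, 0, "edge5", e5)
        plant(ext3 + e3, L - 4 - len(ext3), "edge3", e3)
        tata_start = int(spec.tata_fraction * L)
        w_choice = "A" if rng.random() < 0.5 else "T"
        plant("TATA" + w_choice + "A", tata_start, "tata", "TATAWA")
        reserved = [(0, 4), (L - 4, L), (tata_start, tata_start + 6)]
        plan = [(m, spec.shared_motif_count) for m in shared]
        plan += [(m, spec.family_motif_count) for m in fam_motifs[fam]]
        for motif, count in plan:
            w = motif.width
            lo = max(4, int(spec.motif_window[0] * L))
            hi = min(L - 4 - w, int(spec.motif_window[1] * L) - w)
            if hi <= lo:
                raise ValueError("motif window too narrow for the sequence length")
            for _ in range(count):
                for _attempt in range(30):
                    start = int(rng.integers(lo, hi + 1))
                    if not any(start < e and s < start + w for s, e in reserved):
                        break
                reserved.append((start, start + w))
                plant(_sample_motif_instance(rng, motif, spec.signal_strength), start,
                      "motif", motif.name)
        positives.append(
            LabeledSequence(id=sid, sequence="".join(seq), is_ltr=True, superfamily=sf, family=fam)
        )

    negatives = _generate_negatives(spec, positives, rng)
    truth_rows.extend(_plant_negative_decoys(spec, negatives, fam_motifs, rng))
    truth = pd.DataFrame(truth_rows,
                         columns=["id", "kind", "name", "start", "end", "family", "superfamily"])
    return positives, negatives, truth


def _plant_negative_decoys(spec: SyntheticSpec, negatives, fam_motifs: dict, rng) -> list:
    """Share motif content and some edge signatures with the negatives.

    A ``negative_edge_fraction`` of negatives receives a superfamily edge
    pair, and (when ``match_negative_motifs``) every negative receives as
    many family-motif instances as a positive carries, drawn from the
    pooled family motifs at uniform positions.  This removes single-
    feature shortcuts: only the shared core motifs, the consistent TATA
    placement and the universal edges remain LTR-specific.
    """
    rows = []
    pool = [m for fam in sorted(fam_motifs) for m in fam_motifs[fam]]
    extensions = spec.edge_extensions() if spec.edge_extension else None
    edge_choices = []
    for sf in sorted(spec.superfamily_edges):
        e5, e3 = spec.superfamily_edges[sf]
        ext5, ext3 = extensions[sf] if extensions else ("", "")
        edge_choices.append((e5 + ext5, ext3 + e3))
    n_matched = spec.n_family_motifs * spec.family_motif_count if spec.match_negative_motifs else 0
    for neg in negatives:
        seq = list(neg.sequence)
        L = len(seq)

        def plant(pattern: str, start: int, kind: str, name: str) -> None:
            seq[start : start + len(pattern)] = list(pattern)
            rows.append({"id": neg.id, "kind": kind, "name": name,
                         "start": start, "end": start + len(pattern),
                         "family": None, "superfamily": None})

        # independent 5'/3' decoys: each edge keeps its own signal value
        p5 = spec.negative_edge5_fraction
        p3 = spec.negative_edge3_fraction
        p5 = spec.negative_edge_fraction if p5 is None else p5
        p3 = spec.negative_edge_fraction if p3 is None else p3
        if rng.random() < p5:
            e5 = edge_choices[int(rng.integers(len(edge_choices)))][0]
            plant(e5, 0, "decoy_edge5", e5)
        if rng.random() < p3:
            e3 = edge_choices[int(rng.integers(len(edge_choices)))][1]
            plant(e3, L - len(e3), "decoy_edge3", e3)
        if rng.random() < spec.negative_tata_fraction:
            w_choice = "A" if rng.random() < 0.5 else "T"
            plant("TATA" + w_choice + "A", int(spec.tata_fraction * L), "decoy_tata", "TATAWA")
        if pool and n_matched:
            w = spec.motif_width
            lo = max(4, int(spec.motif_window[0] * L))
            hi = min(L - 4 - w, int(spec.motif_window[1] * L) - w)
            if hi > lo:
                for _ in range(n_matched):
                    motif = pool[int(rng.integers(len(pool)))]
                    start = int(rng.integers(lo, hi + 1))
                    plant(_sample_motif_instance(rng, motif, spec.signal_strength), start,
                          "decoy_motif", motif.name)
        neg.sequence = "".join(seq)
    return rows


def synthetic_genome(rng: np.random.Generator, n_contigs: int = 4, contig_length: int = 20000,
                     block_range: tuple = (500, 2000)) -> list[LabeledSequence]:
    """Patchy-GC contigs: blocks of varying GC content, no LTR structure."""
    contigs = []
    for c in range(n_contigs):
        parts = []
        total = 0
        while total < contig_length:
            block = int(rng.integers(*block_range))
            gc = rng.beta(2, 2)
            p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            parts.append("".join(rng.choice(_BASES, size=block, p=p)))
            total += block
        contigs.append(LabeledSequence(id=f"contig_{c}", sequence="".join(parts)[:contig_length]))
    return contigs


def _generate_negatives(spec: SyntheticSpec, positives, rng: np.random.Generator):
    from .negset import generate_markov, random_uniform_sequences, sample_genomic_windows

    props = spec.negative_proportions
    if not np.isclose(sum(props.values()), 1.0):
        raise ValueError("negative proportions must sum to 1")
    n_by = {k: int(round(v * spec.n_negative)) for k, v in props.items()}
    drift = spec.n_negative - sum(n_by.values())
    if drift and n_by:
        n_by[max(n_by, key=n_by.get)] += drift
    length_sampler = lambda r: int(r.integers(spec.length_range[0], spec.length_range[1] + 1))
    negatives: list[LabeledSequence] = []
    if n_by.get("random"):
        negatives.extend(
            random_uniform_sequences(n_by["random"], length_sampler=length_sampler, seed=rng,
                                     prefix="neg_random")
        )
    if n_by.get("genomic"):
        genome = synthetic_genome(rng, contig_length=max(20000, 4 * spec.length_range[1]))
        negatives.extend(
            sample_genomic_windows(genome, n=n_by["genomic"], length_sampler=length_sampler, seed=rng)
        )
        for i, w in enumerate(negatives[-n_by["genomic"]:]):
            w.id = f"neg_genomic_{i}"
    if n_by.get("markov"):
        by_family: dict = {}
        for p in positives:
            by_family.setdefault(p.family, []).append(p)
        models = [
            (train_markov(group, order=spec.markov_order), [len(p) for p in group])
            for group in by_family.values()
            if group
        ]
        for i in range(n_by["markov"]):
            model, lengths = models[int(rng.integers(len(models)))]
            L = int(lengths[int(rng.integers(len(lengths)))])
            negatives.append(
                LabeledSequence(id=f"neg_markov_{i}",
                                sequence=generate_markov(model, L, rng), is_ltr=False)
            )
    for n in negatives:
        n.is_ltr = False
    return negatives


def shortcut_free_spec(**overrides) -> SyntheticSpec:
    """Conditions for explainability studies: no single-feature shortcut.

    Negatives carry matched family-motif content and a fraction of decoy
    edge signatures, so the only count-level LTR-specific feature is the
    shared core motif, and the only positional signals are the edges and
    the consistently placed TATA box.  ``n_shared_motifs=0`` turns this
    into the planted-TATA construction used for positional-attribution
    analysis.
    """
    params = dict(negative_edge_fraction=0.3, match_negative_motifs=True)
    params.update(overrides)
    return SyntheticSpec(**params)


def difficulty_sweep(spec: SyntheticSpec, signal_strengths) -> list:
    """One dataset per signal strength, all other conditions identical."""
    out = []
    for s in signal_strengths:
        if not 0 <= s <= 1:
            raise ValueError("signal strengths must be in [0, 1]")
        out.append(generate_dataset(dataclasses.replace(spec, signal_strength=s)))
    return out
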