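"""Synthetic demonstration datasets with known planted truth.

These builders produce stand-ins for the kinds of tables the pipeline is run
on in practice (a tissue panel of absolute miRNA abundances, reporter
repression curves).  All values are synthetic: patterns characteristic of
well-known tissue-specific miRNAs are planted at realistic levels on a
low-abundance background, so that screens and fits have a known answer to
recover.
"""

from __future__ import annotations

import pandas as pd

from mirabs.synthetic_data import MOUSE_TISSUES, BRAIN_REGIONS, generate_tissue_abundance_matrix

ON = 5000.0       # comfortably above the 1700 cleavage threshold
MID = 1000.0      # between the 340 off- and 1700 on-thresholds
LOW = 10.0        # background-level expression
DETARGET_LEVEL = 1200.0  # above the 1000 detargeting floor, below the 1700 on-threshold


def synthetic_tissue_panel(seed: int = 0, n_background: int = 150) -> pd.DataFrame:
    """A synthetic miRNA x tissue abundance panel with planted specificity patterns.

    Planted rows (all values molecules per 10 pg total RNA):

    * four single-tissue miRNAs: a liver miRNA at 140,000 (the miR-122
      pattern), two skeletal-muscle miRNAs (miR-1a/miR-133a patterns, which
      also form a muscle-specific pair), and a duodenum miRNA (miR-215
      pattern);
    * four brain-wide miRNAs expressed across all eight brain regions
      (miR-9/124/127/138 patterns) -- brain-specific once regions are grouped;
    * four miRNA pairs co-expressed in exactly one tissue (two in the
      cerebellum, one in the kidney, one in skeletal muscle); the cerebellum
      pair members are also expressed in two organs each and carry
      mid-level expression in one other brain region, so that no unintended
      combination satisfies the pair predicate;
    * two detargeting candidates held between the detargeting floor and the
      cleavage threshold in every tissue except one spared organ (the
      miR-181a/liver and miR-23b/spleen patterns).

    Background rows are log-uniform below 300.  The screens applied with
    default thresholds therefore recover exactly: 4 brain-specific miRNAs
    (grouped), 4 specific pairs, and 2 detargeting candidates.
    """
    planted: list[tuple[str, set, float, float]] = []
    # single-tissue miRNAs
    planted.append(("syn-miR-122", {"liver"}, 140_000.0, LOW))
    planted.append(("syn-miR-1a", {"skeletal_muscle"}, 700_000.0, LOW))
    planted.append(("syn-miR-133a", {"skeletal_muscle"}, ON, LOW))
    planted.append(("syn-miR-215", {"duodenum"}, 3000.0, LOW))
    # brain-wide miRNAs (specific to the brain as a group)
    for name in ("syn-miR-9", "syn-miR-124", "syn-miR-127", "syn-miR-138"):
        planted.append((name, set(BRAIN_REGIONS), ON, LOW))
    # cerebellum pairs: members on in the cerebellum plus two organs, chosen
    # so intended pairs share only the cerebellum while every unintended
    # combination shares two on-tissues (and is therefore not a pair)
    planted.append(("syn-cb1a", {"cerebellum", "spleen", "heart"}, ON, LOW))
    planted.append(("syn-cb1b", {"cerebellum", "lung", "jejunum"}, ON, LOW))
    planted.append(("syn-cb2a", {"cerebellum", "spleen", "lung"}, ON, LOW))
    planted.append(("syn-cb2b", {"cerebellum", "heart", "jejunum"}, ON, LOW))
    # kidney pair
    planted.append(("syn-kd1a", {"kidney"}, ON, LOW))
    planted.append(("syn-kd1b", {"kidney"}, ON, LOW))
    # detargeting candidates: between floor and threshold everywhere but the
    # spared organ, so they never enter the pair or single-tissue screens
    planted.append(("syn-miR-181a", set(MOUSE_TISSUES) - {"liver"}, DETARGET_LEVEL, 100.0))
    planted.append(("syn-miR-23b", set(MOUSE_TISSUES) - {"spleen"}, DETARGET_LEVEL, 100.0))

    mat = generate_tissue_abundance_matrix(None, n_background, planted, seed=seed)
    # mid-level expression in one extra brain region per cerebellum-pair
    # member: blocks pairing with the brain-wide miRNAs without creating an
    # on-tissue
    mat.loc["syn-cb1a", "hippocampus"] = MID
    mat.loc["syn-cb1b", "thalamus"] = MID
    mat.loc["syn-cb2a", "hypothalamus"] = MID
    mat.loc["syn-cb2b", "brainstem"] = MID
    return mat
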