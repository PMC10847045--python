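"""Deterministic synthetic isolate and substrate tables.

The generators emulate the structure of a genome-inferred trait survey
of rhizosphere soil bacteria and a root-exudate metabolite panel so the
whole pipeline runs without any external download:

* isolates span genome sizes of 2-10 Mbp, rrn copy numbers 1-15 and
  minimum generation times from ~1 h (fast copiotrophs) to tens of hours
  (slow oligotrophs); positive root responders are biased toward slower
  growth and organic-acid/auxin transporters, negative responders toward
  fast growth, sugar transporters and higher glycoside-hydrolase gene
  frequencies;
* substrates are drawn from small per-class template sets of real
  metabolite formulas (hexoses, C2-C9 acids, proteinogenic amino acids,
  fatty acids, nucleosides, plant hormones), so NOSC class structure is
  chemically realistic rather than random stoichiometry.

The seed fully determines both tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FixtureConfig", "generate_isolates", "generate_substrates", "SUBSTRATE_TEMPLATES"]

CLASSES = ["sugar", "organic_acid", "amino_acid", "fatty_acid", "nucleotide", "auxin"]

#: (name, formula, charge) templates per chemical class
SUBSTRATE_TEMPLATES: dict[str, list[tuple[str, str, int]]] = {
    "sugar": [
        ("glucose", "C6H12O6", 0),
        ("fructose", "C6H12O6", 0),
        ("galactose", "C6H12O6", 0),
        ("xylose", "C5H10O5", 0),
        ("arabinose", "C5H10O5", 0),
        ("ribose", "C5H10O5", 0),
        ("sucrose", "C12H22O11", 0),
        ("trehalose", "C12H22O11", 0),
        ("maltose", "C12H22O11", 0),
    ],
    "organic_acid": [
        ("acetate", "C2H3O2", -1),
        ("lactate", "C3H5O3", -1),
        ("succinate", "C4H4O4", -2),
        ("malate", "C4H4O5", -2),
        ("citrate", "C6H5O7", -3),
        ("oxalate", "C2O4", -2),
        ("shikimate", "C7H9O5", -1),
        ("salicylate", "C7H5O3", -1),
        ("caffeate", "C9H7O4", -1),
        ("nicotinate", "C6H4NO2", -1),
    ],
    "amino_acid": [
        ("glycine", "C2H5NO2", 0),
        ("alanine", "C3H7NO2", 0),
        ("serine", "C3H7NO3", 0),
        ("threonine", "C4H9NO3", 0),
        ("valine", "C5H11NO2", 0),
        ("leucine", "C6H13NO2", 0),
        ("proline", "C5H9NO2", 0),
        ("glutamate", "C5H8NO4", -1),
        ("aspartate", "C4H6NO4", -1),
        ("phenylalanine", "C9H11NO2", 0),
    ],
    "fatty_acid": [
        ("butyrate", "C4H7O2", -1),
        ("caprylate", "C8H15O2", -1),
        ("laurate", "C12H23O2", -1),
        ("palmitate", "C16H31O2", -1),
        ("stearate", "C18H35O2", -1),
        ("oleate", "C18H33O2", -1),
    ],
    "nucleotide": [
        ("adenosine", "C10H13N5O4", 0),
        ("guanosine", "C10H13N5O5", 0),
        ("cytidine", "C9H13N3O5", 0),
        ("uridine", "C9H12N2O6", 0),
        ("inosine", "C10H12N4O5", 0),
        ("thymidine", "C10H14N2O5", 0),
    ],
    "auxin": [
        ("indole-3-acetate", "C10H9NO2", 0),
        ("indole-3-butyrate", "C12H13NO2", 0),
        ("abscisate", "C15H20O4", 0),
        ("zeatin", "C10H13N5O", 0),
    ],
}


@dataclass
class FixtureConfig:
    """Ranges and proportions of the synthetic survey."""

    n_isolates: int = 12
    n_substrates_per_class: int = 2
    seed: int = 0
    genome_size_range_mbp: tuple[float, float] = (2.0, 10.0)
    rrn_range: tuple[int, int] = (1, 15)
    #: minimum generation time bands (h) for fast and slow organisms
    generation_time_fast_h: tuple[float, float] = (1.0, 4.0)
    generation_time_slow_h: tuple[float, float] = (12.0, 60.0)
    z_X_range: tuple[float, float] = (0.0, 0.1)
    #: Dirichlet concentration for transporter gene frequencies
    z_rho_concentration: float = 4.0
    #: response-group fractions (positive, negative, undefined)
    group_fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)


def generate_isolates(config: FixtureConfig | None = None) -> pd.DataFrame:
    """Synthetic isolate trait table, fully determined by the seed."""
    cfg = config or FixtureConfig()
    if cfg.n_isolates < 1:
        raise ValueError("need at least one isolate")
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_isolates
    n_pos = max(1, round(cfg.group_fractions[0] * n))
    n_neg = max(1, round(cfg.group_fractions[1] * n)) if n > 2 else max(0, n - n_pos)
    n_und = max(0, n - n_pos - n_neg)
    groups = ["positive"] * n_pos + ["negative"] * n_neg + ["undefined"] * n_und

    rows = []
    for k, group in enumerate(groups):
        genome_mbp = rng.uniform(*cfg.genome_size_range_mbp)
        # negative responders: fast growers with many rrn operons and
        # sugar-heavy transporter repertoires; positive responders: slow,
        # organic-acid/auxin oriented
        if group == "negative":
            tg = rng.uniform(*cfg.generation_time_fast_h)
            rrn = int(rng.integers(6, cfg.rrn_range[1] + 1))
            bias = {"sugar": 4.0, "amino_acid": 2.0, "nucleotide": 1.5}
            z_X = rng.uniform(0.5 * cfg.z_X_range[1], cfg.z_X_range[1])
        elif group == "positive":
            tg = rng.uniform(*cfg.generation_time_slow_h)
            rrn = int(rng.integers(cfg.rrn_range[0], 5))
            bias = {"organic_acid": 4.0, "auxin": 2.0, "fatty_acid": 1.5}
            z_X = rng.uniform(cfg.z_X_range[0], 0.5 * cfg.z_X_range[1])
        else:
            fast = rng.random() < 0.5
            tg = rng.uniform(*(cfg.generation_time_fast_h if fast else cfg.generation_time_slow_h))
            rrn = int(rng.integers(*cfg.rrn_range, endpoint=True))
            bias = {}
            z_X = rng.uniform(*cfg.z_X_range)
        alpha = np.array([cfg.z_rho_concentration * bias.get(c, 1.0) for c in CLASSES])
        z_rho = rng.dirichlet(alpha)
        row = {
            "isolate_id": f"iso{k:03d}",
            "genome_size_bp": genome_mbp * 1.0e6,
            "rrn_copies": rrn,
            "min_generation_time_h": tg,
            "r_max": np.log(2.0) / tg,
            "z_X": z_X,
            "response_group": group,
        }
        row.update({f"z_rho_{c}": z_rho[i] for i, c in enumerate(CLASSES)})
        rows.append(row)
    return pd.DataFrame(rows)


def generate_substrates(config: FixtureConfig | None = None) -> pd.DataFrame:
    """Synthetic substrate table drawn from the per-class template sets."""
    cfg = config or FixtureConfig()
    if cfg.n_substrates_per_class < 1:
        raise ValueError("need at least one substrate per class")
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for cls in CLASSES:
        templates = SUBSTRATE_TEMPLATES[cls]
        k = min(cfg.n_substrates_per_class, len(templates))
        idx = rng.choice(len(templates), size=k, replace=False)
        for i in sorted(idx):
            name, formula, charge = templates[i]
            rows.append(
                {"name": name, "class": cls, "formula": formula, "charge": charge}
            )
    return pd.DataFrame(rows)
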