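"""pH-dependent ion geometry.

Distances of bound metal ions (iron in the entry channels; magnesium as a
control) from the assembly's geometric center, and ion–water proximity with
the waters tagged by their persistence category and a hydrogen-bond-range
flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import ModelError, StructureModel
from .persistence import WaterSiteCluster


@dataclass
class WaterContact:
    position: np.ndarray
    distance: float
    category: str
    hydrogen_bond_range: bool


@dataclass
class IonSite:
    element: str
    position: np.ndarray
    chain: str
    occupancy: float
    distance_to_center: float
    nearby_waters: list[WaterContact] = field(default_factory=list)


def geometric_center(model: StructureModel) -> np.ndarray:
    """Unweighted mean of the protein heavy-atom coordinates."""
    coords = model.protein_coords(heavy_only=True)
    if len(coords) == 0:
        raise ModelError("model has no protein atoms")
    return coords.mean(axis=0)


def ion_center_distances(models: Sequence[StructureModel], element: str
                         ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Per condition, the distances of each matching ion to that condition's
    geometric center, with a mean ± sd summary table."""
    element = element.upper()
    per_condition: dict[str, np.ndarray] = {}
    rows = []
    found = False
    for m in models:
        ions = m.ions(element=element)
        center = geometric_center(m)
        d = np.array([np.linalg.norm(i.position - center) for i in ions])
        per_condition[m.condition_label] = d
        if len(d):
            found = True
        rows.append({"condition": m.condition_label, "n_ions": len(d),
                     "mean_distance": float(d.mean()) if len(d) else np.nan,
                     "sd_distance": float(d.std(ddof=1)) if len(d) > 1 else np.nan})
    if not found:
        raise ModelError(f"element {element} not present in any model")
    return per_condition, pd.DataFrame(rows)


def ion_sites(model: StructureModel, element: str) -> list[IonSite]:
    center = geometric_center(model)
    out = []
    for a in model.ions(element=element):
        out.append(IonSite(element=a.element, position=a.position.copy(),
                           chain=a.chain_id, occupancy=a.occupancy,
                           distance_to_center=float(
                               np.linalg.norm(a.position - center))))
    return out


def ion_water_contacts(ion: IonSite, clusters: Sequence[WaterSiteCluster],
                       condition_label: str, shell: float = 5.0,
                       hbond_distance: float = 3.5) -> list[WaterContact]:
    """Waters of one condition within ``shell`` of the ion, sorted by
    distance, tagged with their site's persistence category and flagged when
    within hydrogen-bond range."""
    contacts = []
    for c in clusters:
        for m in c.members:
            if m.condition_label != condition_label:
                continue
            d = float(np.linalg.norm(m.position - ion.position))
            if d <= shell:
                contacts.append(WaterContact(
                    position=m.position.copy(), distance=d, category=c.category,
                    hydrogen_bond_range=d <= hbond_distance))
    contacts.sort(key=lambda c: c.distance)
    ion.nearby_waters = contacts
    return contacts
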