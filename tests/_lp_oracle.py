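"""LP feasibility oracle for steady-state flux, independent of the
topological blocked-reaction audit: flux variability bounds for one
reaction via scipy linprog over S v = 0 with the model's flux bounds."""

from typing import Tuple

import numpy as np
from scipy.optimize import linprog

from gsmkit.model import MetabolicModel


def flux_range(model: MetabolicModel, reaction_id: str) -> Tuple[float, float]:
    met_index = {m: i for i, m in enumerate(sorted(model.metabolites))}
    rxn_ids = sorted(model.reactions)
    rxn_index = {r: j for j, r in enumerate(rxn_ids)}
    S = np.zeros((len(met_index), len(rxn_ids)))
    bounds = []
    for rid in rxn_ids:
        rxn = model.reactions[rid]
        for met, coeff in rxn.stoichiometry.items():
            S[met_index[met], rxn_index[rid]] = coeff
        bounds.append((rxn.lower_bound, rxn.upper_bound))
    j = rxn_index[reaction_id]
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(len(rxn_ids))
        c[j] = sign
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        if not res.success:
            raise RuntimeError(f"LP failed for {reaction_id}: {res.message}")
        out.append(res.x[j])
    lo, hi = min(out), max(out)
    return lo, hi
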