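import numpy as np
import pytest

from moadecon.dose_response import DoseResponseSet, SigmoidFit


@pytest.fixture
def concs9():
    """The 9-point half-log dilution series, 3.16e-9 .. 3.16e-5 M."""
    return 10.0 ** -np.arange(4.5, 9.0, 0.5)[::-1]


def make_fit(log_ic50=-6.0, hill=-1.0, top=100.0, bottom=0.0,
             log_lo=-8.5, log_hi=-4.5, **kw) -> SigmoidFit:
    """A hand-built fit object for closed-form tests."""
    defaults = dict(se_log_ic50=0.01, se_hill=0.01, model="full4p",
                    converged=True, ambiguous=False, rss=0.0, n_points=9,
                    log_conc_min=log_lo, log_conc_max=log_hi)
    defaults.update(kw)
    return SigmoidFit(log_ic50=log_ic50, hill_slope=hill, top=top,
                      bottom=bottom, **defaults)


def logistic(x, log_ic50, hill, top=100.0, bottom=0.0):
    return bottom + (top - bottom) / (1 + 10.0 ** ((log_ic50 - np.log10(x)) * hill))


def make_set(x, y, **kw) -> DoseResponseSet:
    defaults = dict(drug="d", cell_line="l", readout="viability")
    defaults.update(kw)
    return DoseResponseSet(conc_m=x, response=y, **defaults)


def grid_oracle_3p(conc_m, resp, l_grid, h_grid):
    """Exhaustive RSS grid search for the normalised 3-parameter logistic.

    Independent of the package's optimiser: evaluates the model on a dense
    (log IC50, hill) grid and returns the arg-min and its RSS.
    """
    logx = np.log10(np.asarray(conc_m))
    L = np.asarray(l_grid)[:, None, None]
    H = np.asarray(h_grid)[None, :, None]
    pred = 100.0 / (1.0 + 10.0 ** ((L - logx) * H))
    rss = ((pred - np.asarray(resp)) ** 2).sum(axis=-1)
    i, j = np.unravel_index(np.argmin(rss), rss.shape)
    return float(l_grid[i]), float(h_grid[j]), float(rss[i, j])
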