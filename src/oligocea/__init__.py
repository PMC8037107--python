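"""oligocea: cost-effectiveness of local treatments for colorectal liver metastases.

A decision-analytic Markov cohort model comparing hepatic resection,
radiofrequency ablation (RFA) and microwave ablation (MWA) for liver
metastases of oligometastatic colorectal cancer: discounted lifetime
costs and QALYs, dominance and net-monetary-benefit analysis,
probabilistic sensitivity analysis with acceptability curves, and a
starting-age sensitivity sweep.
"""

from importlib import resources as _resources

from .params import (HealthState, ModelConfig, ModelSettings, StrategyParams,
                     ValidationError, builtin_base_case, load_config,
                     save_config, total_treatment_cost, STRATEGY_ORDER)
from .lifetable import LifeTable, LifeTableError, read_lifetable, write_lifetable
from .engine import (CohortTrace, StrategyOutcome, build_transition_matrix,
                     run_all, run_cohort, short_run)
from .cea import CEAResult, Dominance, StrategyCEA, classify_dominance, nmb
from .psa import (CEACCurve, DistributionSpec, PSAResult, ceac,
                  draw_parameters, make_distribution, run_psa)
from .sensitivity import AgeSweepResult, age_sweep
from .synthetic import (DEFAULT_GOMPERTZ, GompertzSpec, MicrosimResult,
                        generate_lifetable, microsim_oracle, random_config)

__version__ = "1.0.0"


def default_lifetable() -> LifeTable:
    """The bundled synthetic 2014-US-style life table (ages 0-100)."""
    ref = _resources.files("oligocea.data") / "synthetic_us2014_lifetable.csv"
    with _resources.as_file(ref) as path:
        return read_lifetable(path)


def default_config_path() -> str:
    """Path to the bundled base-case YAML configuration."""
    return str(_resources.files("oligocea.data") / "base_case.yaml")
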