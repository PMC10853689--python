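"""tricotkit: design, analysis and reporting for triadic comparison trials.

Participants each receive a blind package of three technology options
(positions A/B/C) and report the best and worst per trait. This package
generates the balanced incomplete block designs, turns the responses into
rankings, fits Plackett-Luce worths, detects covariate-driven preference
heterogeneity, computes agro-climatic covariates, and writes trial reports.
"""

from importlib import resources

from .agroclimate import (
    DailyWeather,
    growing_degree_days,
    heat_days,
    link_weather_window,
    max_dry_spell,
)
from .design import (
    ConcurrenceGraph,
    DesignDiagnostics,
    DesignError,
    DesignSpec,
    Package,
    TrialDesign,
    concurrence_graph,
    generate_design,
    kirchhoff_index,
    validate_design,
)
from .io import (
    read_covariates_csv,
    read_design_csv,
    read_observations_csv,
    read_weather_csv,
    write_covariates_csv,
    write_design_csv,
    write_observations_csv,
)
from .plackett import (
    EstimabilityError,
    PLFit,
    SimulationSpec,
    fit_plackett_luce,
    pl_log_likelihood,
    simulate_tricot_responses,
    win_probability,
)
from .pltree import (
    CovariateTable,
    PLTreeNode,
    fit_pl_tree,
    forward_select_covariates,
    split_statistic,
)
from .rankings import (
    Ranking,
    RankingSet,
    ResponseError,
    TricotResponse,
    build_ranking_set,
    response_to_ranking,
    win_graph_connectivity,
)
from .report import ReportBundle, generate_report
from .trial import (
    Project,
    package_qr_payload,
    parse_qr_payload,
    synthesize_trial,
)

__version__ = "0.1.0"


def example_design_path():
    """Path to the bundled 20-package, 10-option example design CSV."""
    return resources.files("tricotkit").joinpath("data/example_design.csv")
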