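{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "termwalk per-trajectory analysis report",
  "type": "object",
  "required": ["version", "config", "trajectory", "stages"],
  "properties": {
    "version": {"type": "string"},
    "config": {"type": "object"},
    "trajectory": {
      "type": "object",
      "required": ["id", "n_samples", "dt_s", "duration_s"],
      "properties": {
        "id": {"type": "string"},
        "n_samples": {"type": "integer"},
        "dt_s": {"type": "number"},
        "duration_s": {"type": "number"},
        "arena_diameter_mm": {"type": ["number", "null"]}
      }
    },
    "stages": {
      "type": "object",
      "properties": {
        "steps": {"required": ["n_steps", "n_zero_steps", "mean_step_mm", "max_step_mm"]},
        "msd": {"required": ["alpha", "mu_alpha", "diffusion_coefficient", "classification"]},
        "structure": {"required": ["q", "zeta", "H", "mu_q"]},
        "spectrum": {"required": ["beta", "segment_length", "n_segments"]},
        "acf": {"required": ["gamma", "r_squared", "classification"]},
        "ifs": {"required": ["n_points", "occupancy_16"]},
        "waiting": {"required": ["exponent", "x_min_s", "n_tail", "ks_distance", "n_bouts"]},
        "turning": {"required": ["n_turns", "bin_centers_deg", "probability"]},
        "zones": {"required": ["wall", "interior", "waiting"]},
        "sampling_rate": {"type": "array"}
      }
    }
  }
}
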