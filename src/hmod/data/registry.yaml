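# Default threat registry: IUCN-style direct-threat taxonomy with land-use
# intensity estimates (best, with min/max bounds, nominally +/-10%).
# in_timeseries: false marks the four threats without multi-year sources,
# excluded from the 1990-2020 time-series set.
threats:
  - class_code: "1"
    class_name: "Residential, commercial & recreation (built-up)"
    threat_code: "1.1"
    threat_name: "Housing & urban areas"
    intensities:
      - {subtype: default, best: 0.85, min: 0.77, max: 0.94}
    sources: [builtup_fused]
    in_timeseries: true
    in_current: true
  - class_code: "1"
    class_name: "Residential, commercial & recreation (built-up)"
    threat_code: "1.2"
    threat_name: "Commercial & industrial areas"
    intensities:
      - {subtype: default, best: 0.86, min: 0.78, max: 0.95}
    sources: [builtup_fused, commercial_polygons]
    in_timeseries: true
    in_current: true
  - class_code: "1"
    class_name: "Residential, commercial & recreation (built-up)"
    threat_code: "1.3"
    threat_name: "Tourism & recreation areas"
    intensities:
      - {subtype: default, best: 0.38, min: 0.34, max: 0.41}
    sources: [builtup_fused, tourism_polygons]
    in_timeseries: false
    in_current: true
  - class_code: "2"
    class_name: "Agriculture"
    threat_code: "2.1"
    threat_name: "Annual & perennial non-timber croplands"
    intensities:
      - {subtype: single, best: 0.39, min: 0.35, max: 0.43}
      - {subtype: double, best: 0.53, min: 0.48, max: 0.58}
      - {subtype: triple, best: 0.67, min: 0.60, max: 0.74}
    sources: [cropland_fused, rotation_classes]
    in_timeseries: true
    in_current: true
  - class_code: "2"
    class_name: "Agriculture"
    threat_code: "2.2"
    threat_name: "Wood & pulp plantations"
    intensities:
      - {subtype: tree_crop, best: 0.30, min: 0.27, max: 0.33}
      - {subtype: planted_forest, best: 0.06, min: 0.06, max: 0.07}
    sources: [plantation_mask, canopy_cover]
    in_timeseries: true
    in_current: true
  - class_code: "2"
    class_name: "Agriculture"
    threat_code: "2.3"
    threat_name: "Livestock farming & ranching"
    intensities:
      - {subtype: default, best: 0.30, min: 0.27, max: 0.33}
    sources: [landcover, livestock_density]
    in_timeseries: true
    in_current: true
  - class_code: "3"
    class_name: "Energy production & mining"
    threat_code: "3.1"
    threat_name: "Oil & gas production"
    intensities:
      - {subtype: default, best: 0.81, min: 0.73, max: 0.89}
    sources: [flare_points, well_points]
    in_timeseries: true
    in_current: true
  - class_code: "3"
    class_name: "Energy production & mining"
    threat_code: "3.2"
    threat_name: "Mining & quarrying"
    intensities:
      - {subtype: default, best: 0.81, min: 0.73, max: 0.89}
    sources: [mine_polygons]
    in_timeseries: false
    in_current: true
  - class_code: "3"
    class_name: "Energy production & mining"
    threat_code: "3.3"
    threat_name: "Renewable energy"
    intensities:
      - {subtype: default, best: 0.78, min: 0.70, max: 0.86}
    sources: [turbine_points]
    in_timeseries: true
    in_current: true
  - class_code: "4"
    class_name: "Transportation & service corridors"
    threat_code: "4.1"
    threat_name: "Roads & railways"
    intensities:
      - {subtype: highway, best: 0.81, min: 0.73, max: 0.89}
      - {subtype: secondary, best: 0.76, min: 0.68, max: 0.83}
      - {subtype: residential, best: 0.66, min: 0.59, max: 0.72}
      - {subtype: track, best: 0.09, min: 0.08, max: 0.10}
      - {subtype: rail, best: 0.76, min: 0.68, max: 0.84}
    sources: [road_lines, rail_lines]
    in_timeseries: false
    in_current: true
  - class_code: "4"
    class_name: "Transportation & service corridors"
    threat_code: "4.2"
    threat_name: "Utility infrastructure & service lines"
    intensities:
      - {subtype: powerline, best: 0.38, min: 0.34, max: 0.41}
      - {subtype: nightlights, best: 0.38, min: 0.34, max: 0.41}
    sources: [powerline_lines, nightlights]
    in_timeseries: true
    in_current: true
  - class_code: "5"
    class_name: "Biological resource use"
    threat_code: "5.3"
    threat_name: "Logging & wood harvesting"
    intensities:
      - {subtype: default, best: 0.30, min: 0.27, max: 0.33}
    sources: [forest_loss, forest_height, burn_year]
    in_timeseries: true
    in_current: true
  - class_code: "6"
    class_name: "Human accessibility"
    threat_code: "6.1"
    threat_name: "Human accessibility"
    intensities:
      - {subtype: default, best: 0.09, min: 0.08, max: 0.10}
    sources: [population_density, trail_lines, cost_surface]
    in_timeseries: true
    in_current: true
  - class_code: "7"
    class_name: "Natural systems modification"
    threat_code: "7.2"
    threat_name: "Dams & water management"
    intensities:
      - {subtype: default, best: 0.78, min: 0.70, max: 0.86}
    sources: [reservoir_polygons, water_mask]
    in_timeseries: true
    in_current: true
  - class_code: "9"
    class_name: "Pollution"
    threat_code: "9.4"
    threat_name: "Garbage & solid waste"
    intensities:
      - {subtype: default, best: 0.83, min: 0.75, max: 0.92}
    sources: [landfill_polygons]
    in_timeseries: false
    in_current: true
  - class_code: "9"
    class_name: "Pollution"
    threat_code: "9.5"
    threat_name: "Air-borne pollutants"
    intensities:
      - {subtype: default, best: 0.09, min: 0.08, max: 0.10}
    sources: [no2_column]
    in_timeseries: true
    in_current: true
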