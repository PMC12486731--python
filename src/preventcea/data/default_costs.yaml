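# Default micro-costing configuration for the eight delivery strategies.
# All monetary values in NOK; all durations in hours.
unit_costs:
  # Loaded group-leader rate (school health nurse wage x 1.4 social-cost
  # multiplier); supplied directly as the loaded rate.
  loaded_hourly_rate: 529.0
  social_cost_multiplier: 1.4
  workbooks_low_parental: 1345.0   # per group, brochure-only parental arm
  workbooks_high_parental: 2540.0  # per group, five parent sessions
  mfs_app: 225.0                   # per group, charged only under feedback
  supervision_fee: 1000.0          # flat per-group supervisor fee
resources:
  child_session_duration: 1.0
  parent_session_duration: 1.5
  prep_per_session: 1.0
  mfs_review_hours: 8.0            # one hour/week over the 8-week course
  supervision_hours_per_leader: 4.0
  recruitment_hours_per_leader: 2.0
  group_leaders: 2
  group_size: 5
  child_sessions:
    long: 16                       # 16 in-person sessions
    hybrid: 8                      # 8 in-person (+8 web-based, no extra leader time)
  parent_sessions:
    high: 5
    low: 0
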