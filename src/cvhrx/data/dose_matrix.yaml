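# Starting physical-activity dose by (weight status x activity status).
# Placeholder defaults satisfying the ordering constraint that severely
# obese, inactive patients begin with shorter durations and no more
# sessions than overweight, inactive patients. Fully overridable.
overweight:
  inactive:          {minutes_per_session: 30, sessions_per_week: 3, intensity_target: moderate}
  somewhat_active:   {minutes_per_session: 35, sessions_per_week: 4, intensity_target: moderate}
  moderately_active: {minutes_per_session: 40, sessions_per_week: 4, intensity_target: moderate}
  active:            {minutes_per_session: 45, sessions_per_week: 5, intensity_target: vigorous}
obese:
  inactive:          {minutes_per_session: 25, sessions_per_week: 3, intensity_target: moderate}
  somewhat_active:   {minutes_per_session: 30, sessions_per_week: 3, intensity_target: moderate}
  moderately_active: {minutes_per_session: 35, sessions_per_week: 4, intensity_target: moderate}
  active:            {minutes_per_session: 40, sessions_per_week: 5, intensity_target: vigorous}
severe_obese:
  inactive:          {minutes_per_session: 20, sessions_per_week: 3, intensity_target: moderate}
  somewhat_active:   {minutes_per_session: 25, sessions_per_week: 3, intensity_target: moderate}
  moderately_active: {minutes_per_session: 30, sessions_per_week: 4, intensity_target: moderate}
  active:            {minutes_per_session: 35, sessions_per_week: 4, intensity_target: moderate}
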