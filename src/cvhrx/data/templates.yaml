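# Check-in message templates. Placeholders are {named}; every template is
# linted at load time against the controlling-language lexicon
# (should / must / have to / need to) so the wording stays autonomy-supportive.
- id: advance_pa
  tone_class: advance
  body: >-
    Great work, {first_name}! You met your activity goal. If it feels right,
    you could try {new_goal_minutes} minutes this week. You may pick any
    activity you enjoy, like {activity}.
- id: hold_pa
  tone_class: hold
  body: >-
    Nice effort, {first_name}. Keeping your goal at {new_goal_minutes} minutes
    this week may help it become a habit. You could mix in {activity} whenever
    it sounds fun.
- id: ease_pa
  tone_class: ease
  body: >-
    Thanks for checking in, {first_name}. Some weeks are busy! An easier goal
    of {new_goal_minutes} minutes may feel more doable. You could start with a
    short session of {activity}.
- id: advance_diet
  tone_class: advance
  body: >-
    Way to go, {first_name}! Your food choices are on track. You may keep
    building on your {behavior} goal this week.
- id: hold_diet
  tone_class: hold
  body: >-
    Thanks for the update, {first_name}. Sticking with your {behavior} goal
    another week could make it feel easier.
- id: ease_diet
  tone_class: ease
  body: >-
    Thanks for being honest, {first_name}. Small steps count — you could pick
    one green food to add this week for your {behavior} goal.
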