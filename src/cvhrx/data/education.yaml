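# Educational text blocks for the prescription document. Keys match diet
# behaviors plus general blocks. Wording follows the autonomy-supportive
# style (no should/must/have to/need to) and short sentences.
physical_activity:
  title: "Why moving matters"
  body: >-
    Being active can lift your mood, help you sleep, and build a healthy
    heart. Any activity counts. You may start small and build up. Picking
    something fun makes it easier to keep going.
stoplight_overview:
  title: "Green, yellow, red foods"
  body: >-
    Green foods are anytime foods — high in nutrition and low in fat. Yellow
    foods are sometimes foods. Red foods are rarely foods. You could fill
    most of your plate with green foods.
family_tips:
  title: "Tips for families"
  body: >-
    Change is easier together. Families may plan one active outing a week,
    keep green snacks where everyone can see them, and celebrate small wins.
fruit:
  title: "About fruit"
  body: >-
    Whole fruit brings fiber and vitamins. Two or more servings a day is a
    healthy target. Fresh, frozen, or canned in juice all count.
vegetable:
  title: "About vegetables"
  body: >-
    Vegetables fill you up with few calories. You could add one vegetable to
    lunch and one to dinner. Crunchy raw veggies make easy snacks.
whole_grains:
  title: "About whole grains"
  body: >-
    Whole grains keep more fiber and nutrients than refined grains. Swapping
    white bread for whole-wheat is an easy first step.
ssb:
  title: "About sugary drinks"
  body: >-
    Sugary drinks add sugar without filling you up. Water and low-fat milk
    are great choices. You may keep a water bottle handy during the day.
snacking:
  title: "About snacking"
  body: >-
    Snacks can be part of healthy eating. Green snacks like fruit or veggie
    sticks give energy that lasts. You could plan snacks ahead of time.
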