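category_id	label	phrase
hopelessness	Hopelessness	no hope
hopelessness	Hopelessness	hopeless
hopelessness	Hopelessness	nothing will ever change
hopelessness	Hopelessness	no future for me
loneliness	Loneliness	so lonely
loneliness	Loneliness	feel lonely
loneliness	Loneliness	nobody is with me
loneliness	Loneliness	completely isolated
previous_attempt	Previous suicide attempt	tried before to end it
previous_attempt	Previous suicide attempt	my past attempt
previous_attempt	Previous suicide attempt	attempted it once
previous_attempt	Previous suicide attempt	overdosed last year
self_harm	Self-harm	cut myself
self_harm	Self-harm	hurt myself
self_harm	Self-harm	burned my arm
self_harm	Self-harm	scratch my skin
depression	Depressive symptoms	deeply depressed
depression	Depressive symptoms	cannot get out of bed
depression	Depressive symptoms	crying all day
depression	Depressive symptoms	feel empty inside
thwarted_belongingness	Thwarted belongingness	do not belong
thwarted_belongingness	Thwarted belongingness	left out of everything
thwarted_belongingness	Thwarted belongingness	no one needs me
thwarted_belongingness	Thwarted belongingness	excluded from the group
perceived_burdensomeness	Perceived burdensomeness	burden on everyone
perceived_burdensomeness	Perceived burdensomeness	better off without me
perceived_burdensomeness	Perceived burdensomeness	weigh everyone down
perceived_burdensomeness	Perceived burdensomeness	drag on my family
psychopathology	Psychopathology	my diagnosis
psychopathology	Psychopathology	hearing voices
psychopathology	Psychopathology	panic attacks
psychopathology	Psychopathology	psychiatric ward
family_suicide_history	Family suicide history	suicide in my family
family_suicide_history	Family suicide history	my father took his life
family_suicide_history	Family suicide history	my sister killed herself
family_suicide_history	Family suicide history	family history of suicide
bullying	Bullying / cyberbullying	bullied at school
bullying	Bullying / cyberbullying	they bully me
bullying	Bullying / cyberbullying	cyberbullying
bullying	Bullying / cyberbullying	mocked online
sexual_harassment	Sexual harassment	harassed me
sexual_harassment	Sexual harassment	unwanted touching
sexual_harassment	Sexual harassment	sexual comments
sexual_harassment	Sexual harassment	he groped me
adverse_life_events	Adverse life events	lost my job
adverse_life_events	Adverse life events	parents divorced
adverse_life_events	Adverse life events	we lost our home
adverse_life_events	Adverse life events	the accident changed everything
lgbtq_stress	LGBTQ-related stress	came out as gay
lgbtq_stress	LGBTQ-related stress	they reject my identity
lgbtq_stress	LGBTQ-related stress	closeted
lgbtq_stress	LGBTQ-related stress	transphobic remarks
immigration_stress	Immigration-related stress	new immigrant
immigration_stress	Immigration-related stress	far from my homeland
immigration_stress	Immigration-related stress	visa problems
immigration_stress	Immigration-related stress	do not speak the language
impulsivity	Impulsivity	acted without thinking
impulsivity	Impulsivity	on impulse
impulsivity	Impulsivity	could not stop myself
impulsivity	Impulsivity	reckless decision
perfectionism	Perfectionism	never good enough
perfectionism	Perfectionism	must be perfect
perfectionism	Perfectionism	fear of any mistake
perfectionism	Perfectionism	the highest standards
emotional_distress	Emotional distress	overwhelmed
emotional_distress	Emotional distress	cannot cope anymore
emotional_distress	Emotional distress	falling apart
emotional_distress	Emotional distress	too much pain
social_withdrawal	Social withdrawal	stopped seeing friends
social_withdrawal	Social withdrawal	stay in my room
social_withdrawal	Social withdrawal	avoid everyone
social_withdrawal	Social withdrawal	shut the door on the world
entrapment	Entrapment	trapped
entrapment	Entrapment	no escape
entrapment	Entrapment	stuck with no options
entrapment	Entrapment	walls closing in
hyperarousal	Hyperarousal	cannot sleep at all
hyperarousal	Hyperarousal	heart racing
hyperarousal	Hyperarousal	on edge
hyperarousal	Hyperarousal	jumpy and restless
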